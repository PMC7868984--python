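"""SV presence/absence matrix, PHYLIP export and distance-based tree.

The samples x merged-SV binary matrix treats force-called absence as a true
0 (no missing-data state). PHYLIP export is relaxed sequential, suitable as
input for external maximum-likelihood tools; internally a neighbor-joining
tree on Hamming distances provides a reproducible clustering of samples,
with midpoint rooting used when a rooted topology is needed (e.g. to test
whether sample groups come out monophyletic).
"""

from __future__ import annotations

import logging
import re
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .model import ConsistencyError, SVCluster, SVMatrix

log = logging.getLogger(__name__)


def build_matrix(clusters: Sequence[SVCluster],
                 samples: Sequence[str]) -> SVMatrix:
    """Binary presence matrix: cell(s, c) = 1 iff sample s is present in
    cluster c. Invariant (all-0/all-1) columns are retained."""
    samples = list(samples)
    if len(set(samples)) != len(samples):
        raise ConsistencyError(f"duplicate sample ids: {samples}")
    cells = np.zeros((len(samples), len(clusters)), dtype=np.int8)
    ids = []
    for j, cl in enumerate(clusters):
        ids.append(cl.cluster_id or f"c{j}")
        missing = set(samples) - set(cl.presence)
        if missing:
            raise ConsistencyError(
                f"cluster {ids[-1]} lacks presence for {sorted(missing)}")
        for i, s in enumerate(samples):
            cells[i, j] = 1 if cl.presence[s] else 0
    return SVMatrix(samples=samples, cluster_ids=ids, cells=cells)


def _sanitize(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]", "_", name)[:10]


def _unique_names(samples: Sequence[str]) -> list[str]:
    """Sanitize and truncate to 10 characters, disambiguating collisions
    with a numeric suffix; unresolvable collisions raise."""
    names: list[str] = []
    used: set[str] = set()
    for s in samples:
        base = _sanitize(s)
        name = base
        k = 0
        while name in used:
            k += 1
            suffix = str(k)
            if len(suffix) >= 10:
                raise ConsistencyError(
                    f"cannot disambiguate sample name {s!r}; colliding "
                    f"names so far: {sorted(used)}")
            name = base[:10 - len(suffix)] + suffix
        used.add(name)
        names.append(name)
    return names


def write_phylip(matrix: SVMatrix, path) -> None:
    """Relaxed sequential PHYLIP: header "n_samples n_sites", then one line
    per sample with the (sanitized, <=10 char, uniquely truncated) name and
    its 0/1 string."""
    names = _unique_names(matrix.samples)
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.samples)} {len(matrix.cluster_ids)}\n")
        for name, row in zip(names, matrix.cells):
            fh.write(f"{name:<12}{''.join(str(int(v)) for v in row)}\n")


def read_phylip(path) -> SVMatrix:
    """Read back a relaxed sequential binary PHYLIP file."""
    with open(path) as fh:
        header = fh.readline().split()
        n, m = int(header[0]), int(header[1])
        samples, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            seq = seq.strip()
            samples.append(name)
            rows.append([int(c) for c in seq])
    if len(samples) != n or any(len(r) != m for r in rows):
        raise ConsistencyError(f"PHYLIP dimensions disagree with header in {path}")
    return SVMatrix(samples=samples,
                    cluster_ids=[f"site{j}" for j in range(m)],
                    cells=np.array(rows, dtype=np.int8))


def distance_matrix(matrix: SVMatrix) -> DistanceMatrix:
    """Pairwise Hamming proportion (fraction of differing sites)."""
    if len(matrix.samples) < 2:
        raise ValueError("need at least two samples")
    if matrix.cells.shape[1] == 0:
        raise ValueError("cannot compute distances over zero sites")
    cells = matrix.cells.astype(np.int16)
    diff = (cells[:, None, :] != cells[None, :, :]).mean(axis=2)
    return DistanceMatrix(diff, ids=matrix.samples)


def nj_tree(distances: DistanceMatrix) -> TreeNode:
    """Unrooted neighbor-joining tree; deterministic under fixed input order.

    For fewer than three samples a trivial star tree is returned with a
    warning.
    """
    n = len(distances.ids)
    if n < 3:
        log.warning("neighbor joining needs >= 3 taxa, got %d; "
                    "returning a trivial tree", n)
        children = [TreeNode(name=i, length=float(distances[i, distances.ids[0]]))
                    for i in distances.ids]
        return TreeNode(children=children)
    tree = nj(distances)
    # guard against negative NJ branch lengths (standard clamp at 0)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def midpoint_root(tree: TreeNode) -> TreeNode:
    return tree.root_at_midpoint()


def is_monophyletic(rooted_tree: TreeNode, tip_names: Sequence[str]) -> bool:
    """True iff ``tip_names`` form a clade of the rooted tree (or its
    complement does, i.e. the split exists)."""
    tips = set(tip_names)
    all_tips = {t.name for t in rooted_tree.tips()}
    if not tips <= all_tips:
        raise KeyError(f"unknown tips: {sorted(tips - all_tips)}")
    if tips == all_tips or len(tips) == 1:
        return True
    lca = rooted_tree.lca([t for t in rooted_tree.tips()
                           if t.name in tips])
    clade = {t.name for t in lca.tips()}
    return clade == tips or (all_tips - clade) == tips


def to_newick(tree: TreeNode) -> str:
    return str(tree).strip()


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")


def write_distances_tsv(distances: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        ids = list(distances.ids)
        fh.write("sample\t" + "\t".join(ids) + "\n")
        for i in ids:
            fh.write(i + "\t" +
                     "\t".join(f"{distances[i, j]:.6f}" for j in ids) + "\n")
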