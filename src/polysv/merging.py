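"""Cross-sample SV merging by breakpoint proximity, force-calling and
platform concordance.

Two records merge when they lie on the same chromosome (and share a type,
when type-aware), and both the left and the right breakpoint differ by at
most ``max_breakpoint_distance``. Clusters are the transitive closure of
that relation (single linkage), so members of a cluster can drift further
apart than the distance along a chain — the same behaviour as a
SURVIVOR-style merge with "max distance between breakpoints" semantics.

Force-calling is geometric re-genotyping: a call set record supports a
cluster when its breakpoints both land within the merge distance of the
cluster representative; each record supports at most one cluster (the
nearest by |dpos| + |dend|, ties to the leftmost).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import ConsistencyError, SVCallSet, SVCluster, SVRecord


@dataclass(frozen=True)
class MergeParams:
    max_breakpoint_distance: int = 1000
    type_aware: bool = True
    strand_aware: bool = False   # accepted for interface parity; no-op
    size_aware: bool = False     # accepted for interface parity; no-op

    def __post_init__(self) -> None:
        if self.max_breakpoint_distance < 0:
            raise ValueError("max_breakpoint_distance must be >= 0")


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _median_int(values: Sequence[int]) -> int:
    return int(math.floor(float(np.median(values)) + 0.5))


def merge_callsets(callsets: Sequence[SVCallSet],
                   params: MergeParams = MergeParams()) -> list[SVCluster]:
    """Single-linkage clustering of records from several call sets.

    Every input record belongs to exactly one cluster; unmatched records form
    singletons. Representative coordinates are member medians. Output is
    sorted by (chrom, rep_pos) with stable ids.
    """
    if not callsets:
        raise ValueError("need at least one call set")
    samples = [cs.sample_id for cs in callsets]
    if len(set(samples)) != len(samples):
        raise ConsistencyError(f"duplicate sample ids in merge: {samples}")

    strata: dict[tuple, list[SVRecord]] = {}
    for cs in callsets:
        for rec in cs:
            key = (rec.chrom, rec.svtype) if params.type_aware else (rec.chrom,)
            strata.setdefault(key, []).append(rec)

    d = params.max_breakpoint_distance
    clusters: list[SVCluster] = []
    for key in sorted(strata):
        recs = sorted(strata[key], key=lambda r: (r.pos, r.end, r.sample_id))
        n = len(recs)
        uf = _UnionFind(n)
        # records sorted by pos: only a sliding window of candidates can
        # satisfy |dpos| <= d, so the scan is near-linear for sparse data
        left = 0
        for i in range(n):
            while recs[i].pos - recs[left].pos > d:
                left += 1
            for j in range(left, i):
                if abs(recs[i].end - recs[j].end) <= d:
                    uf.union(i, j)
        groups: dict[int, list[SVRecord]] = {}
        for i in range(n):
            groups.setdefault(uf.find(i), []).append(recs[i])
        for root in sorted(groups):
            members = groups[root]
            by_sample: dict[str, list[SVRecord]] = {}
            for m in members:
                by_sample.setdefault(m.sample_id, []).append(m)
            clusters.append(SVCluster(
                cluster_id="",  # assigned after global sort
                chrom=members[0].chrom,
                svtype=members[0].svtype,
                rep_pos=_median_int([m.pos for m in members]),
                rep_end=_median_int([m.end for m in members]),
                rep_len=_median_int([m.svlen for m in members]),
                members=by_sample,
                presence={s: (s in by_sample) for s in samples},
            ))
    clusters.sort(key=lambda c: (c.chrom, c.rep_pos, c.svtype, c.rep_end))
    for i, cl in enumerate(clusters):
        cl.cluster_id = f"SV{i:06d}_{cl.chrom}_{cl.svtype}"
    return clusters


def force_call(clusters: Sequence[SVCluster], callset: SVCallSet,
               params: MergeParams = MergeParams()) -> list[bool]:
    """Presence of each cluster in one call set by breakpoint re-matching.

    A record matches a cluster when types agree (if type-aware) and both
    |pos - rep_pos| and |end - rep_end| are within the merge distance. Each
    record is assigned to its nearest matching cluster only.
    """
    d = params.max_breakpoint_distance
    # index clusters by stratum, sorted by rep_pos for windowed lookup
    strata: dict[tuple, list[tuple[int, SVCluster]]] = {}
    for idx, cl in enumerate(clusters):
        key = (cl.chrom, cl.svtype) if params.type_aware else (cl.chrom,)
        strata.setdefault(key, []).append((idx, cl))
    for lst in strata.values():
        lst.sort(key=lambda t: (t[1].rep_pos, t[0]))

    present = [False] * len(clusters)
    for rec in callset:
        key = (rec.chrom, rec.svtype) if params.type_aware else (rec.chrom,)
        best: tuple[int, int, int] | None = None  # (distance, rep_pos, idx)
        for idx, cl in strata.get(key, ()):
            if cl.rep_pos - rec.pos > d:
                break
            dpos = abs(rec.pos - cl.rep_pos)
            dend = abs(rec.end - cl.rep_end)
            if dpos <= d and dend <= d:
                cand = (dpos + dend, cl.rep_pos, idx)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            present[best[2]] = True
    return present


def concordance(presence_a: Sequence[bool],
                presence_b: Sequence[bool]) -> dict:
    """Fraction of merged clusters genotyped in both of two call sets.

    Returns {n_total, n_both, pct_both} with the percentage rounded to one
    decimal; an empty cluster set leaves the percentage None.
    """
    if len(presence_a) != len(presence_b):
        raise ConsistencyError(
            f"presence vectors differ in length: "
            f"{len(presence_a)} vs {len(presence_b)}")
    n_total = len(presence_a)
    n_both = sum(1 for a, b in zip(presence_a, presence_b) if a and b)
    pct = round(100.0 * n_both / n_total, 1) if n_total else None
    return {"n_total": n_total, "n_both": n_both, "pct_both": pct}
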