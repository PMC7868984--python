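"""Overlap of SV calls with gene models, genomic windows and QTL intervals.

Overlap semantics follow the bedtools-intersect default the field uses: a
gene "carries" an SV when they share at least one base. Deletions and
inversions occupy their reference span [pos, end]; insertions are point
events at pos. An intragenic SV is *exonic* when it overlaps at least one
exon base, otherwise *intronic*. A non-genic SV within the promoter flank
upstream of a gene's 5' end (strand-aware) is labelled *promoter* for that
gene; everything else is *intergenic*.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .model import GeneModel, GenomeLayout, SVCallSet, SVRecord, percent

LOCATION_LABELS = ("exonic", "intronic", "promoter", "intergenic")


@dataclass
class AnnotationResult:
    """Per-sample gene/SV overlap bookkeeping.

    ``gene_hits`` maps gene_id -> SV indices overlapping the gene body;
    ``promoter_hits`` maps gene_id -> non-genic SV indices in its promoter;
    ``pair_labels`` maps (sv index, gene_id) -> exonic/intronic/promoter;
    ``sv_label`` maps every SV index to its single genome-wide label with
    precedence exonic > intronic > promoter > intergenic.
    """

    sample_id: str
    n_sv: int
    gene_hits: dict[str, set[int]] = field(default_factory=dict)
    promoter_hits: dict[str, set[int]] = field(default_factory=dict)
    pair_labels: dict[tuple[int, str], str] = field(default_factory=dict)
    sv_label: dict[int, str] = field(default_factory=dict)

    @property
    def intragenic_sv(self) -> set[int]:
        return {i for i, lab in self.sv_label.items()
                if lab in ("exonic", "intronic")}


def read_gff3(path) -> list[GeneModel]:
    """Load gene models (gene + exon features) from a GFF3 file.

    Uses gffutils with an in-memory database; the ``ID`` attribute of gene
    features is the gene id, exons attach via ``Parent``.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = sorted((e.start, e.end)
                       for e in db.children(g, featuretype="exon"))
        genes.append(GeneModel(
            gene_id=g.id, chrom=g.seqid, start=g.start, end=g.end,
            strand=g.strand if g.strand in ("+", "-") else "+",
            exons=tuple(exons)))
    return genes


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(f"{g.chrom}\tpolysv\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for k, (s, e) in enumerate(g.exons, start=1):
                fh.write(f"{g.chrom}\tpolysv\texon\t{s}\t{e}\t.\t{g.strand}"
                         f"\t.\tID={g.gene_id}.exon{k};Parent={g.gene_id}\n")


def _promoter_interval(gene: GeneModel, flank: int) -> tuple[int, int] | None:
    """1-based inclusive promoter interval upstream of the 5' end."""
    if flank <= 0:
        return None
    if gene.strand == "+":
        start = max(1, gene.start - flank)
        end = gene.start - 1
    else:
        start = gene.end + 1
        end = gene.end + flank
    if start > end:
        return None
    return (start, end)


def intersect_genes(callset: SVCallSet, genes: Sequence[GeneModel],
                    promoter_flank: int = 2000) -> AnnotationResult:
    """Annotate every SV of one sample against the gene models."""
    gene_tree: dict[str, IntervalTree] = {}
    prom_tree: dict[str, IntervalTree] = {}
    by_id = {g.gene_id: g for g in genes}
    for g in genes:
        gene_tree.setdefault(g.chrom, IntervalTree()).addi(
            g.start - 1, g.end, g.gene_id)
        prom = _promoter_interval(g, promoter_flank)
        if prom is not None:
            prom_tree.setdefault(g.chrom, IntervalTree()).addi(
                prom[0] - 1, prom[1], g.gene_id)

    res = AnnotationResult(sample_id=callset.sample_id, n_sv=len(callset))
    for i, rec in enumerate(callset):
        lo, hi = rec.span  # 0-based half-open
        hits = gene_tree.get(rec.chrom, IntervalTree()).overlap(lo, hi)
        if hits:
            labels = set()
            for iv in hits:
                gene = by_id[iv.data]
                exonic = any(not (hi <= es - 1 or lo >= ee)
                             for es, ee in gene.exons)
                label = "exonic" if exonic else "intronic"
                labels.add(label)
                res.gene_hits.setdefault(gene.gene_id, set()).add(i)
                res.pair_labels[(i, gene.gene_id)] = label
            res.sv_label[i] = "exonic" if "exonic" in labels else "intronic"
        else:
            proms = prom_tree.get(rec.chrom, IntervalTree()).overlap(lo, hi)
            if proms:
                for iv in proms:
                    res.promoter_hits.setdefault(iv.data, set()).add(i)
                    res.pair_labels[(i, iv.data)] = "promoter"
                res.sv_label[i] = "promoter"
            else:
                res.sv_label[i] = "intergenic"
    return res


def count_intragenic(result: AnnotationResult, n_total_genes: int) -> dict:
    """Gene-level and event-level intragenic statistics.

    ``pct_genes_hit`` is over all genes in the annotation; ``exon_pct`` is
    the share of intragenic SV events that touch an exon. Both are None
    when their denominator is zero.
    """
    n_genes_hit = len(result.gene_hits)
    intragenic = result.intragenic_sv
    n_intragenic = len(intragenic)
    n_exonic = sum(1 for i in intragenic if result.sv_label[i] == "exonic")
    return {
        "n_genes_hit": n_genes_hit,
        "n_intragenic_sv": n_intragenic,
        "n_exonic_sv": n_exonic,
        "n_intronic_sv": n_intragenic - n_exonic,
        "pct_genes_hit": percent(n_genes_hit, n_total_genes)
        if n_total_genes > 0 else None,
        "exon_pct": percent(n_exonic, n_intragenic) if n_intragenic else None,
    }


def window_counts(callset: SVCallSet, layout: GenomeLayout,
                  window: int = 1_000_000,
                  kinds: Iterable[str] = ("DEL", "INS")):
    """Per-window SV counts across the genome.

    Windows tile each chromosome from position 1 (last window truncated);
    an SV is counted once, in the window containing its left breakpoint.
    Returns a pandas DataFrame with chrom/start/end and one column per kind.
    """
    import pandas as pd

    kinds = tuple(kinds)
    rows = []
    index: dict[tuple[str, int], int] = {}
    for chrom, length, _ in layout.chromosomes:
        n_win = (length + window - 1) // window
        for w in range(n_win):
            index[(chrom, w)] = len(rows)
            rows.append({
                "chrom": chrom,
                "start": w * window + 1,
                "end": min((w + 1) * window, length),
                **{k: 0 for k in kinds},
            })
    for rec in callset:
        if rec.svtype not in kinds:
            continue
        key = (rec.chrom, (rec.pos - 1) // window)
        if key in index:
            rows[index[key]][rec.svtype] += 1
    return pd.DataFrame(rows)


def subgenome_rates(counts_per_chrom: Mapping[str, int],
                    layout: GenomeLayout) -> dict:
    """Per-Mbp SV rates of the A vs C subgenomes with a rank-sum test.

    Per-chromosome rates (count / length in Mbp) are compared between the
    two subgenomes with a two-sided Wilcoxon rank-sum (Mann-Whitney U) test,
    exact when chromosome counts permit and values are untied.
    """
    chroms_a = layout.subgenome_chroms("A")
    chroms_c = layout.subgenome_chroms("C")
    if len(chroms_a) < 2 or len(chroms_c) < 2:
        raise ValueError(
            "need at least two chromosomes per subgenome for a rate test")
    rates = {c: counts_per_chrom.get(c, 0) / (layout.length(c) / 1e6)
             for c in chroms_a + chroms_c}
    a = np.array([rates[c] for c in chroms_a])
    c = np.array([rates[c] for c in chroms_c])
    rate_a = float(np.sum([counts_per_chrom.get(x, 0) for x in chroms_a])
                   / (sum(layout.length(x) for x in chroms_a) / 1e6))
    rate_c = float(np.sum([counts_per_chrom.get(x, 0) for x in chroms_c])
                   / (sum(layout.length(x) for x in chroms_c) / 1e6))
    pooled = np.concatenate([a, c])
    if np.all(pooled == pooled[0]):
        p_value = 1.0
    else:
        exact = (len(a) <= 12 and len(c) <= 12
                 and len(np.unique(pooled)) == len(pooled))
        res = stats.mannwhitneyu(a, c, alternative="two-sided",
                                 method="exact" if exact else "asymptotic")
        p_value = float(res.pvalue)
    return {
        "rate_A": rate_a,
        "rate_C": rate_c,
        "per_chrom_rates": rates,
        "p_value": min(p_value, 1.0),
    }


@dataclass
class VennReport:
    """Cardinalities of all Venn regions over up to four group sets.

    ``regions`` maps a sorted tuple of group names to the number of
    elements belonging to exactly those groups. When more than four groups
    are given, ``regions`` is empty and ``pairwise`` holds |Gi & Gj| instead.
    """

    group_sets: dict[str, set]
    regions: dict[tuple[str, ...], int] = field(default_factory=dict)
    pairwise: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def common_all(self) -> int:
        key = tuple(sorted(self.group_sets))
        return self.regions.get(key, 0)

    def unique_to(self, group: str) -> int:
        return self.regions.get((group,), 0)


def group_gene_sets(per_sample_sets: Mapping[str, set],
                    groups: Mapping[str, str],
                    mode: str = "union") -> VennReport:
    """Combine per-sample gene sets into per-group sets and Venn regions.

    A group's set is the union (default) or intersection of its member
    samples' sets. Venn-region cardinalities are reported for up to four
    groups; beyond that only pairwise intersections are reported.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be union or intersection, got {mode!r}")
    group_sets: dict[str, set] = {}
    for sample, group in groups.items():
        if sample not in per_sample_sets:
            raise KeyError(f"no gene set for sample {sample!r}")
        s = per_sample_sets[sample]
        if group not in group_sets:
            group_sets[group] = set(s)
        elif mode == "union":
            group_sets[group] |= s
        else:
            group_sets[group] &= s
    names = sorted(group_sets)
    report = VennReport(group_sets=group_sets)
    if len(names) > 4:
        for g1, g2 in itertools.combinations(names, 2):
            report.pairwise[(g1, g2)] = len(group_sets[g1] & group_sets[g2])
        return report
    universe = set().union(*group_sets.values()) if group_sets else set()
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set(universe)
            for g in combo:
                inside &= group_sets[g]
            for g in names:
                if g not in combo:
                    inside -= group_sets[g]
            report.regions[combo] = len(inside)
    return report


@dataclass
class QTLCandidates:
    """Genes in a QTL interval carrying SV in exactly one of two samples."""

    interval: tuple[str, int, int]
    interval_mbp: float
    n_genes: int
    candidates_a: list[str]
    candidates_b: list[str]
    n_common_dropped: int


def qtl_candidates(chrom: str, start: int, end: int,
                   genes: Sequence[GeneModel],
                   sv_genes_a: set, sv_genes_b: set,
                   keywords: Sequence[str] | None = None,
                   gene_annotations: Mapping[str, str] | None = None
                   ) -> QTLCandidates:
    """Prioritize QTL-interval genes by sample-specific SV presence.

    Genes overlapping the interval and carrying SV in exactly one of the two
    samples (symmetric difference) are candidates; genes hit in both are
    dropped. With ``keywords`` and per-gene annotation text, candidates are
    further restricted to annotations containing any keyword
    (case-insensitive).
    """
    if end <= start:
        raise ValueError(f"empty interval {chrom}:{start}-{end}")
    in_interval = {g.gene_id for g in genes
                   if g.chrom == chrom and g.end >= start and g.start <= end}
    a = set(sv_genes_a) & in_interval
    b = set(sv_genes_b) & in_interval
    common = a & b
    cand_a = sorted(a - b)
    cand_b = sorted(b - a)
    if keywords:
        ann = gene_annotations or {}
        kw = [k.lower() for k in keywords]
        keep = lambda g: any(k in ann.get(g, "").lower() for k in kw)
        cand_a = [g for g in cand_a if keep(g)]
        cand_b = [g for g in cand_b if keep(g)]
    return QTLCandidates(
        interval=(chrom, start, end),
        interval_mbp=round((end - start + 1) / 1e6, 1),
        n_genes=len(in_interval),
        candidates_a=cand_a,
        candidates_b=cand_b,
        n_common_dropped=len(common),
    )


def amplicon_implied_length(ref_amplicon_bp: int, alt_amplicon_bp: int) -> int:
    """SV length implied by two PCR amplicon sizes across a breakpoint.

    Positive values mean a deletion in the sample with the shorter amplicon;
    negative values an insertion.
    """
    if ref_amplicon_bp <= 0 or alt_amplicon_bp <= 0:
        raise ValueError("amplicon sizes must be positive")
    return ref_amplicon_bp - alt_amplicon_bp
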