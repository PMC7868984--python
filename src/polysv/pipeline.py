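"""End-to-end orchestration: filter -> merge -> annotate -> CNV -> matrix ->
tree, from a YAML config, with auditable intermediates.

Every stage writes its products under the output directory so each step can
be inspected or recomputed independently; a run log records package version,
parameters and per-stage row counts. Re-running with the same config and
inputs is bit-identical (all randomness in this pipeline lives in the
synthetic generator, which is seeded).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .model import ConfigError, GenomeLayout, SVCallSet, percent
from .filtering import FilterPolicy, quality_filter, summarize
from .merging import MergeParams, merge_callsets, force_call, concordance
from .annotation import (
    count_intragenic,
    group_gene_sets,
    intersect_genes,
    read_gff3,
    subgenome_rates,
    window_counts,
)
from .cnv import (
    block_medians,
    call_duplications,
    chromosome_stats,
    detect_chromosome_loss,
    read_bedgraph,
    segments_to_bed,
)
from .phylogeny import (
    build_matrix,
    distance_matrix,
    midpoint_root,
    nj_tree,
    to_newick,
    write_newick,
    write_phylip,
)
from .vcf_io import read_sniffles_vcf, write_vcf, write_multisample_vcf

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "samples", "gff3", "chrom_sizes", "filter", "merge", "window_size",
    "promoter_flank", "cnv_k", "loss_fraction", "out_dir", "seed",
}
_SAMPLE_KEYS = {"id", "vcf", "group", "platform", "depth"}
_FILTER_KEYS = {"drop_types", "min_size", "max_size"}
_MERGE_KEYS = {"max_breakpoint_distance", "type_aware"}


@dataclass
class SampleSpec:
    id: str
    vcf: str
    group: str
    platform: str = ""
    depth: str | None = None


@dataclass
class PipelineConfig:
    samples: list[SampleSpec]
    gff3: str
    chrom_sizes: str
    out_dir: str
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    merge_params: MergeParams = field(default_factory=MergeParams)
    window_size: int = 1_000_000
    promoter_flank: int = 2000
    cnv_k: float = 1.0
    loss_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.samples:
            raise ConfigError("empty sample table")
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"duplicate sample ids: {ids}")
        for s in self.samples:
            if not Path(s.vcf).exists():
                raise ConfigError(f"sample {s.id}: VCF not found: {s.vcf}")
            if s.depth and not Path(s.depth).exists():
                raise ConfigError(f"sample {s.id}: depth not found: {s.depth}")
        for path, what in ((self.gff3, "gff3"), (self.chrom_sizes, "chrom_sizes")):
            if not Path(path).exists():
                raise ConfigError(f"{what} file not found: {path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for req in ("samples", "gff3", "chrom_sizes", "out_dir"):
            if req not in raw:
                raise ConfigError(f"missing required config key: {req}")
        samples = []
        for entry in raw["samples"]:
            bad = set(entry) - _SAMPLE_KEYS
            if bad:
                raise ConfigError(f"unknown sample keys: {sorted(bad)}")
            samples.append(SampleSpec(**entry))
        fp_kwargs = {}
        for k, v in (raw.get("filter") or {}).items():
            if k not in _FILTER_KEYS:
                raise ConfigError(f"unknown filter key: {k}")
            fp_kwargs[k] = frozenset(v) if k == "drop_types" else v
        mp_kwargs = {}
        for k, v in (raw.get("merge") or {}).items():
            if k not in _MERGE_KEYS:
                raise ConfigError(f"unknown merge key: {k}")
            mp_kwargs[k] = v
        return cls(
            samples=samples,
            gff3=raw["gff3"],
            chrom_sizes=raw["chrom_sizes"],
            out_dir=raw["out_dir"],
            filter_policy=FilterPolicy(**fp_kwargs),
            merge_params=MergeParams(**mp_kwargs),
            window_size=int(raw.get("window_size", 1_000_000)),
            promoter_flank=int(raw.get("promoter_flank", 2000)),
            cnv_k=float(raw.get("cnv_k", 1.0)),
            loss_fraction=float(raw.get("loss_fraction", 0.1)),
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class RunReport:
    per_sample: dict[str, dict]
    n_clusters: int
    subgenome: dict
    venn_regions: dict
    newick: str
    loss_flags: dict[str, list[str]]
    out_dir: str


def _stage(name: str, sample: str | None = None):
    where = f"stage {name}" + (f" (sample {sample})" if sample else "")
    log.info("running %s", where)
    return where


def run(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline and write the report bundle to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logfile = out / "run.log"
    loglines: list[str] = [
        f"polysv {__version__}",
        f"filter: {config.filter_policy}",
        f"merge: {config.merge_params}",
        f"window_size: {config.window_size}",
        f"promoter_flank: {config.promoter_flank}",
        f"cnv_k: {config.cnv_k}",
        f"loss_fraction: {config.loss_fraction}",
        f"seed: {config.seed}",
    ]
    layout = GenomeLayout.from_tsv(config.chrom_sizes)
    genes = read_gff3(config.gff3)
    loglines.append(f"genes: {len(genes)}")
    samples = [s.id for s in config.samples]
    groups = {s.id: s.group for s in config.samples}

    filtered: dict[str, SVCallSet] = {}
    per_sample: dict[str, dict] = {}
    gene_sets: dict[str, set] = {}
    for spec in config.samples:
        where = _stage("filter", spec.id)
        try:
            raw_cs = read_sniffles_vcf(spec.vcf, spec.id)
            f_cs = quality_filter(raw_cs, config.filter_policy)
        except Exception as exc:
            raise ConfigError(f"{where} failed: {exc}") from exc
        filtered[spec.id] = f_cs
        write_vcf(f_cs, out / f"{spec.id}.filtered.vcf", layout=layout)
        summ = summarize(f_cs)
        ann = intersect_genes(f_cs, genes, config.promoter_flank)
        intr = count_intragenic(ann, n_total_genes=len(genes))
        gene_sets[spec.id] = set(ann.gene_hits)
        per_sample[spec.id] = {
            "sample": spec.id,
            "group": spec.group,
            "platform": spec.platform,
            "n_raw": len(raw_cs),
            "n_filtered": summ.n_sv,
            "n_intragenic": intr["n_intragenic_sv"],
            "n_genes_hit": intr["n_genes_hit"],
            "pct_genes_hit": intr["pct_genes_hit"],
            "exon_pct": intr["exon_pct"],
            "max_size": summ.max_size,
            "median_size": summ.median_size,
            "per_chrom": summ.per_chrom,
        }
        loglines.append(f"{spec.id}: raw={len(raw_cs)} filtered={summ.n_sv} "
                        f"intragenic={intr['n_intragenic_sv']}")

    _stage("merge")
    clusters = merge_callsets(list(filtered.values()), config.merge_params)
    write_multisample_vcf(clusters, samples, out / "merged.vcf", layout=layout)
    loglines.append(f"clusters: {len(clusters)}")

    _stage("windows")
    import pandas as pd

    for kind in ("DEL", "INS"):
        frames = []
        for sid in samples:
            df = window_counts(filtered[sid], layout, config.window_size,
                               kinds=(kind,))
            df = df.rename(columns={kind: sid})
            frames.append(df.set_index(["chrom", "start", "end"])[sid])
        pd.concat(frames, axis=1).reset_index().to_csv(
            out / f"window_counts.{kind}.tsv", sep="\t", index=False)

    _stage("subgenome")
    counts_total: dict[str, int] = {}
    for sid in samples:
        for rec in filtered[sid]:
            counts_total[rec.chrom] = counts_total.get(rec.chrom, 0) + 1
    try:
        sg = subgenome_rates(counts_total, layout)
    except ValueError as exc:
        sg = {"rate_A": None, "rate_C": None, "p_value": None,
              "note": str(exc)}
    with open(out / "subgenome_rates.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        for k in ("rate_A", "rate_C", "p_value"):
            fh.write(f"{k}\t{sg[k]}\n")

    _stage("venn")
    venn = group_gene_sets(gene_sets, groups)
    with open(out / "gene_set_venn.tsv", "w") as fh:
        fh.write("groups\tn_genes\n")
        for combo, n in sorted(venn.regions.items()):
            fh.write(f"{'&'.join(combo)}\t{n}\n")

    _stage("matrix")
    matrix = build_matrix(clusters, samples)
    write_phylip(matrix, out / "sv_matrix.phy")
    _stage("tree")
    if len(samples) >= 3 and matrix.cells.shape[1] > 0:
        dm = distance_matrix(matrix)
        tree = midpoint_root(nj_tree(dm))
        newick = to_newick(tree)
        write_newick(tree, out / "sv_tree.nwk")
    else:
        newick = ""
        loglines.append("tree skipped: fewer than 3 samples or empty matrix")

    loss_flags: dict[str, list[str]] = {}
    for spec in config.samples:
        if not spec.depth:
            continue
        where = _stage("cnv", spec.id)
        try:
            tracks = read_bedgraph(spec.depth)
            blocks_by_chrom = {c: block_medians(t) for c, t in tracks.items()}
            segments = []
            for chrom, blocks in blocks_by_chrom.items():
                stats = chromosome_stats(blocks)
                segments.extend(call_duplications(blocks, stats, k=config.cnv_k))
            segments_to_bed(segments, out / f"{spec.id}.cnv.bed")
            if len(blocks_by_chrom) >= 2:
                loss_flags[spec.id] = detect_chromosome_loss(
                    blocks_by_chrom, config.loss_fraction)
            loglines.append(f"{spec.id}: cnv_segments={len(segments)} "
                            f"lost={loss_flags.get(spec.id, [])}")
        except Exception as exc:
            raise ConfigError(f"{where} failed: {exc}") from exc

    pd.DataFrame([
        {k: v for k, v in row.items() if k != "per_chrom"}
        for row in per_sample.values()
    ]).to_csv(out / "sample_summary.tsv", sep="\t", index=False)
    with open(out / "per_chrom_counts.tsv", "w") as fh:
        fh.write("sample\tchrom\tn_sv\n")
        for sid in samples:
            for chrom in layout.names:
                fh.write(f"{sid}\t{chrom}\t"
                         f"{per_sample[sid]['per_chrom'].get(chrom, 0)}\n")
    with open(logfile, "w") as fh:
        fh.write("\n".join(loglines) + "\n")

    return RunReport(
        per_sample=per_sample,
        n_clusters=len(clusters),
        subgenome=sg,
        venn_regions={"&".join(k): v for k, v in venn.regions.items()},
        newick=newick,
        loss_flags=loss_flags,
        out_dir=str(out),
    )
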