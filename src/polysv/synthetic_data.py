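"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generator emulates what multi-sample long-read SV calling over an
allopolyploid genome produces, at desk scale:

* an A/C-subgenome genome layout (default four chromosomes, 36 Mbp total)
  with non-overlapping gene models;
* ecotype-structured call sets: each sample carries its group's shared SV
  plus private SV, with log-normal sizes (median ~300 bp, clamped to
  30..30 000 bp) and a configurable A-subgenome rate excess (default 1.3x);
* caller artefacts ("decoys") that the quality filter must remove:
  UNRESOLVED calls, split-read-only calls, translocations and duplications;
* per-sample breakpoint jitter emulating platform noise between ONT and
  PacBio observations of the same event;
* coverage tracks with spiked duplications and whole-chromosome loss.

Every draw comes from a stage-specific numpy Generator seeded as
``[master_seed, stage offset]``, so regenerating any one product is
bit-identical and independent of the others. Planted truth is tracked for
every emitted record, so tests can compare pipeline output against truth
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .model import GeneModel, GenomeLayout, SVCallSet, SVRecord
from .cnv import DepthTrack

# RNG stream offsets, one per generator stage
_STREAM_GENES = 1
_STREAM_EVENTS = 2
_STREAM_DECOYS = 3
_STREAM_JITTER = 4
_STREAM_COVERAGE = 5


def default_layout() -> GenomeLayout:
    return GenomeLayout([
        ("A01", 10_000_000), ("A02", 8_000_000),
        ("C01", 10_000_000), ("C02", 8_000_000),
    ])


@dataclass
class SimParams:
    """Generator configuration; defaults are the study conditions emulated.

    ``groups`` maps group name to sample count; samples are named
    ``<group>_<i>``. ``decoy_rates`` are fractions of the raw emitted call
    set, chosen so the default filter removes roughly the 55-60% of raw
    calls a stringent long-read filter discards. ``subgenome_bias`` scales
    the per-Mbp placement rate on A-subgenome chromosomes relative to C.
    """

    seed: int = 42
    layout: GenomeLayout = field(default_factory=default_layout)
    groups: dict[str, int] = field(default_factory=lambda: {
        "winter": 4, "semi_winter": 4, "spring": 4})
    n_shared_per_group: int = 60
    n_private_per_sample: int = 15
    size_log_median: float = 300.0
    size_log_sd: float = 1.3
    min_size: int = 30
    max_size: int = 30_000
    type_mix: dict[str, float] = field(default_factory=lambda: {
        "DEL": 0.45, "INS": 0.45, "INV": 0.10})
    decoy_rates: dict[str, float] = field(default_factory=lambda: {
        "unresolved": 0.28, "sr_only": 0.15, "tra": 0.07, "dup": 0.07})
    platform_jitter_sd: float = 50.0
    subgenome_bias: float = 1.3
    intragenic_fraction: float = 0.22
    gene_density: float = 40.0          # genes per Mbp
    exons_per_gene: int = 4
    coverage_mean: float = 30.0
    coverage_noise_sd: float = 2.0
    coverage_noise_block: int = 100     # bp of constant noise (autocorrelation)
    planted_duplications: list[tuple[str, int, int, float]] = field(
        default_factory=lambda: [("A01", 2_000_001, 50, 2.0)])
    lost_chromosomes: dict[str, list[str]] = field(default_factory=dict)
    min_event_spacing: int = 2500

    def __post_init__(self) -> None:
        for name, frac in self.decoy_rates.items():
            if not 0 <= frac < 1:
                raise ValueError(f"decoy rate {name} outside [0, 1)")
        if sum(self.decoy_rates.values()) >= 1:
            raise ValueError("decoy rates must sum to < 1")
        total_mix = sum(self.type_mix.values())
        if abs(total_mix - 1) > 1e-9:
            self.type_mix = {k: v / total_mix for k, v in self.type_mix.items()}

    @property
    def samples(self) -> list[str]:
        return [f"{g}_{i + 1}" for g in self.groups for i in range(self.groups[g])]

    @property
    def group_of(self) -> dict[str, str]:
        return {f"{g}_{i + 1}": g for g in self.groups
                for i in range(self.groups[g])}

    @property
    def platform_of(self) -> dict[str, str]:
        return {s: ("ONT" if i % 2 == 0 else "PacBio")
                for i, s in enumerate(self.samples)}

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class PlantedSV:
    """One true simulated event (pre-jitter coordinates)."""

    event_id: str
    chrom: str
    pos: int
    end: int
    svtype: str
    svlen: int
    scope: str                 # "group:<name>" or "private:<sample>"
    samples: tuple[str, ...]
    target_gene: str | None = None


@dataclass
class TruthSet:
    """Everything the generator planted, keyed for exact test comparison."""

    params: SimParams
    genes: list[GeneModel]
    events: list[PlantedSV]
    true_records: dict[str, list[SVRecord]]
    decoy_records: dict[str, list[SVRecord]]
    decoy_kinds: dict[str, list[str]]
    group_of: dict[str, str]
    platform_of: dict[str, str]

    def genes_with_planted_sv(self) -> set[str]:
        return {e.target_gene for e in self.events if e.target_gene}

    def to_json(self, path) -> None:
        payload = {
            "samples": list(self.group_of),
            "group_of": self.group_of,
            "platform_of": self.platform_of,
            "n_genes": len(self.genes),
            "events": [asdict(e) for e in self.events],
            "decoy_counts": {s: len(v) for s, v in self.decoy_records.items()},
            "lost_chromosomes": self.params.lost_chromosomes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# gene models

def _generate_genes(params: SimParams) -> list[GeneModel]:
    rng = params.rng(_STREAM_GENES)
    genes: list[GeneModel] = []
    n_exons = params.exons_per_gene
    for chrom, length, _ in params.layout.chromosomes:
        n_genes = int(round(params.gene_density * length / 1e6))
        if n_genes < 1:
            continue
        slot = length // n_genes
        for i in range(n_genes):
            gene_len = int(rng.integers(1500, 3501))
            gene_len = min(gene_len, slot - 2)
            margin = slot - gene_len - 1
            start = i * slot + 1 + int(rng.integers(0, max(margin, 1)))
            end = start + gene_len - 1
            n_seg = 2 * n_exons - 1
            cuts = np.sort(rng.choice(np.arange(1, gene_len), size=n_seg - 1,
                                      replace=False))
            bounds = np.concatenate([[0], cuts, [gene_len]])
            exons = tuple((start + int(bounds[k]), start + int(bounds[k + 1]) - 1)
                          for k in range(n_seg) if k % 2 == 0)
            genes.append(GeneModel(
                gene_id=f"{chrom}g{i + 1:04d}", chrom=chrom,
                start=start, end=end,
                strand="+" if i % 2 == 0 else "-",
                exons=exons))
    return genes


def emit_gff(params: SimParams, path=None) -> list[GeneModel]:
    """Generate (and optionally write as GFF3) the synthetic gene models.

    Gene placement is one gene per equal-width slot, so genes never overlap
    and the count per chromosome is exactly density x length.
    """
    genes = _generate_genes(params)
    if path is not None:
        from .annotation import write_gff3

        write_gff3(genes, path)
    return genes


# ---------------------------------------------------------------------------
# SV panel

class _Placer:
    """Rejection-samples event positions with a minimum spacing so distinct
    planted events never merge into one cluster by accident."""

    def __init__(self, params: SimParams):
        self.params = params
        self.occupied: dict[str, list[tuple[int, int]]] = {
            c: [] for c in params.layout.names}
        weights = []
        for chrom, length, label in params.layout.chromosomes:
            w = length * (params.subgenome_bias if label == "A" else 1.0)
            weights.append(w)
        total = sum(weights)
        self.chrom_probs = [w / total for w in weights]

    def _fits(self, chrom: str, pos: int, end: int) -> bool:
        spacing = self.params.min_event_spacing
        lo, hi = pos - spacing, end + spacing
        return all(e < lo or s > hi for s, e in self.occupied[chrom])

    def place(self, rng: np.random.Generator, svlen: int, svtype: str,
              gene: GeneModel | None = None,
              genes: Sequence[GeneModel] | None = None
              ) -> tuple[str, int, int]:
        """Place one event; with ``genes`` given, resample the target gene
        on collision so occupied gene neighbourhoods do not stall placement."""
        span = svlen if svtype in ("DEL", "INV", "DUP") else 1
        for attempt in range(2000):
            if genes is not None:
                gene = genes[int(rng.integers(0, len(genes)))]
            if gene is not None:
                chrom = gene.chrom
                length = self.params.layout.length(chrom)
                g_lo, g_hi = gene.start, gene.end
                pos = int(rng.integers(g_lo, g_hi + 1))
            else:
                idx = int(rng.choice(len(self.chrom_probs),
                                     p=self.chrom_probs))
                chrom, length, _ = self.params.layout.chromosomes[idx]
                if length <= span + 2:
                    continue
                pos = int(rng.integers(1, length - span))
            end = pos + span if svtype in ("DEL", "INV", "DUP") else pos
            if end > length:
                continue
            if self._fits(chrom, pos, end):
                self.occupied[chrom].append((pos, end))
                return chrom, pos, end
        raise RuntimeError(
            "could not place event without violating minimum spacing; "
            "reduce event counts or spacing")


def _draw_size(rng: np.random.Generator, params: SimParams) -> int:
    size = rng.lognormal(mean=np.log(params.size_log_median),
                         sigma=params.size_log_sd)
    return int(np.clip(round(size), params.min_size, params.max_size))


def _draw_type(rng: np.random.Generator, params: SimParams) -> str:
    kinds = sorted(params.type_mix)
    probs = [params.type_mix[k] for k in kinds]
    return str(rng.choice(kinds, p=probs))


def simulate_panel(params: SimParams) -> tuple[TruthSet, dict[str, SVCallSet]]:
    """Generate the multi-sample SV panel and its truth set.

    Each sample's call set is its group's shared events plus its private
    events (both observed with per-sample breakpoint jitter) plus its
    decoys; samples listed in ``lost_chromosomes`` have all calls on those
    chromosomes removed, mirroring a chromosome replaced by its homoeolog.
    """
    genes = _generate_genes(params)
    rng_ev = params.rng(_STREAM_EVENTS)
    placer = _Placer(params)
    genic_genes = list(genes)
    events: list[PlantedSV] = []
    counter = 0

    def make_events(n: int, scope: str, samples: tuple[str, ...]):
        nonlocal counter
        for _ in range(n):
            svtype = _draw_type(rng_ev, params)
            svlen = _draw_size(rng_ev, params)
            intragenic = (bool(genic_genes)
                          and rng_ev.random() < params.intragenic_fraction)
            chrom, pos, end = placer.place(
                rng_ev, svlen, svtype,
                genes=genic_genes if intragenic else None)
            target = None
            if intragenic:
                target = next(g.gene_id for g in genic_genes
                              if g.chrom == chrom and g.start <= pos <= g.end)
            counter += 1
            events.append(PlantedSV(
                event_id=f"ev{counter:05d}", chrom=chrom, pos=pos, end=end,
                svtype=svtype, svlen=svlen, scope=scope, samples=samples,
                target_gene=target))

    group_members = {g: [s for s in params.samples
                         if params.group_of[s] == g]
                     for g in params.groups}
    for g in params.groups:
        make_events(params.n_shared_per_group, f"group:{g}",
                    tuple(group_members[g]))
    for s in params.samples:
        make_events(params.n_private_per_sample, f"private:{s}", (s,))

    # observed (jittered) true records per sample
    rng_jit = params.rng(_STREAM_JITTER)
    true_records: dict[str, list[SVRecord]] = {s: [] for s in params.samples}
    for ev in events:
        for s in ev.samples:
            if params.platform_jitter_sd > 0:
                delta = int(round(rng_jit.normal(0, params.platform_jitter_sd)))
            else:
                delta = 0
            length = params.layout.length(ev.chrom)
            pos = int(np.clip(ev.pos + delta, 1,
                              length - (ev.svlen if ev.svtype != "INS" else 1)))
            end = pos + ev.svlen if ev.svtype != "INS" else pos
            true_records[s].append(SVRecord(
                sample_id=s, chrom=ev.chrom, pos=pos, end=end,
                svtype=ev.svtype, svlen=ev.svlen, filter_status="PASS",
                support_types=frozenset({"AL", "SR"}),
                read_support=int(rng_jit.poisson(params.coverage_mean / 2) + 2),
                precise=True))

    # decoys per sample
    rng_dec = params.rng(_STREAM_DECOYS)
    rate_sum = sum(params.decoy_rates.values())
    decoy_records: dict[str, list[SVRecord]] = {s: [] for s in params.samples}
    decoy_kinds: dict[str, list[str]] = {s: [] for s in params.samples}
    for s in params.samples:
        n_true = len(true_records[s])
        for kind in sorted(params.decoy_rates):
            rate = params.decoy_rates[kind]
            n_decoy = int(round(n_true * rate / (1 - rate_sum)))
            for _ in range(n_decoy):
                svlen = _draw_size(rng_dec, params)
                if kind == "tra":
                    svtype, status, support = "TRA", "PASS", {"AL"}
                elif kind == "dup":
                    svtype, status, support = "DUP", "PASS", {"AL"}
                elif kind == "unresolved":
                    svtype = _draw_type(rng_dec, params)
                    status, support = "UNRESOLVED", {"AL"}
                else:  # sr_only
                    svtype = _draw_type(rng_dec, params)
                    status, support = "PASS", {"SR"}
                chrom, pos, end = placer.place(rng_dec, svlen, svtype)
                if svtype == "TRA":
                    end = pos
                decoy_records[s].append(SVRecord(
                    sample_id=s, chrom=chrom, pos=pos, end=end,
                    svtype=svtype, svlen=svlen, filter_status=status,
                    support_types=frozenset(support),
                    read_support=int(rng_dec.poisson(6) + 1),
                    precise=(status == "PASS")))
                decoy_kinds[s].append(kind)

    callsets: dict[str, SVCallSet] = {}
    for s in params.samples:
        lost = set(params.lost_chromosomes.get(s, []))
        if lost:
            true_records[s] = [r for r in true_records[s]
                               if r.chrom not in lost]
            keep = [i for i, r in enumerate(decoy_records[s])
                    if r.chrom not in lost]
            decoy_records[s] = [decoy_records[s][i] for i in keep]
            decoy_kinds[s] = [decoy_kinds[s][i] for i in keep]
        callsets[s] = SVCallSet(
            sample_id=s,
            records=true_records[s] + decoy_records[s],
            provenance=f"simulated ({params.platform_of[s]})")

    truth = TruthSet(params=params, genes=genes, events=events,
                     true_records=true_records, decoy_records=decoy_records,
                     decoy_kinds=decoy_kinds, group_of=params.group_of,
                     platform_of=params.platform_of)
    return truth, callsets


# ---------------------------------------------------------------------------
# coverage

def simulate_coverage(params: SimParams, sample: str | None = None
                      ) -> tuple[dict[str, DepthTrack], list[dict], list[str]]:
    """Per-chromosome depth tracks with planted duplications and losses.

    Depth is the coverage mean plus rounded normal noise held constant over
    ``coverage_noise_block`` bp chunks (long-read depth is autocorrelated;
    chunk width 1 gives i.i.d. per-base noise), floored at zero. Planted
    duplications multiply depth by their fold; lost chromosomes are scaled
    to 2% of the mean. Returns (tracks, duplication truth, lost chroms).
    """
    rng = params.rng(_STREAM_COVERAGE)
    lost = list(params.lost_chromosomes.get(sample, [])) if sample else []
    tracks: dict[str, DepthTrack] = {}
    dup_truth: list[dict] = []
    block = max(1, int(params.coverage_noise_block))
    for chrom, length, _ in params.layout.chromosomes:
        n_chunks = (length + block - 1) // block
        noise = rng.normal(params.coverage_mean, params.coverage_noise_sd,
                           size=n_chunks)
        depth = np.repeat(np.round(noise), block)[:length]
        for (dchrom, dstart, dblocks, fold) in params.planted_duplications:
            if dchrom != chrom:
                continue
            dend = min(dstart + dblocks * 1000 - 1, length)
            depth[dstart - 1:dend] = np.round(depth[dstart - 1:dend] * fold)
            dup_truth.append({"chrom": chrom, "start": dstart, "end": dend,
                              "n_blocks": dblocks, "fold": fold})
        if chrom in lost:
            depth = np.round(depth * 0.02)
        tracks[chrom] = DepthTrack(chrom=chrom,
                                   depth=np.clip(depth, 0, None).astype(np.int32))
    return tracks, dup_truth, lost
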