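"""Domain model shared across the polysv pipeline.

Coordinates follow the VCF convention everywhere a user sees them: 1-based,
inclusive. Interval arithmetic inside overlap code converts to 0-based
half-open at the point of use and never leaks that convention outward.

An insertion (INS) is a point event: ``end == pos`` and the inserted length
lives only in ``svlen``. Spanning events (DEL, INV, DUP) satisfy
``end >= pos``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

SV_TYPES = ("DEL", "INS", "INV", "DUP", "TRA")
SUPPORT_TYPES = ("AL", "SR", "NR")
FILTER_STATUSES = ("PASS", "UNRESOLVED")


class PolysvError(Exception):
    """Base class for all polysv errors."""


class MalformedRecordError(PolysvError):
    """A VCF data line violates the structural-variant dialect."""


class FormatError(PolysvError):
    """A file cannot be parsed as the expected format."""


class ConsistencyError(PolysvError):
    """Inputs that must agree (sample lists, dimensions) do not."""


class ConfigError(PolysvError):
    """A pipeline configuration is invalid."""


@dataclass(frozen=True)
class SVRecord:
    """One caller-reported structural variant.

    ``support_types`` mirrors the caller's SUPTYPE evidence classes:
    within-alignment (AL), split-read (SR) and noisy-read (NR). Calls whose
    evidence is contained in single read alignments (AL) are the
    high-confidence class retained by the default quality filter.
    """

    sample_id: str
    chrom: str
    pos: int
    end: int
    svtype: str
    svlen: int
    filter_status: str = "PASS"
    support_types: frozenset[str] = frozenset({"AL"})
    read_support: int = 0
    precise: bool = True

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise MalformedRecordError(f"unknown SVTYPE {self.svtype!r}")
        if self.filter_status not in FILTER_STATUSES:
            raise MalformedRecordError(
                f"unknown FILTER {self.filter_status!r}")
        if self.pos < 1:
            raise MalformedRecordError(f"pos must be >= 1, got {self.pos}")
        if self.svlen <= 0:
            raise MalformedRecordError(f"svlen must be > 0, got {self.svlen}")
        if self.svtype == "INS":
            if self.end != self.pos:
                raise MalformedRecordError(
                    f"INS requires end == pos, got {self.pos}..{self.end}")
        elif self.end < self.pos:
            raise MalformedRecordError(
                f"end {self.end} < pos {self.pos} for {self.svtype}")
        if not set(self.support_types) <= set(SUPPORT_TYPES):
            raise MalformedRecordError(
                f"unknown support types {set(self.support_types) - set(SUPPORT_TYPES)}")
        if self.read_support < 0:
            raise MalformedRecordError("read_support must be >= 0")

    @property
    def span(self) -> tuple[int, int]:
        """Affected reference interval as 0-based half-open (INS: 1 bp point)."""
        if self.svtype == "INS":
            return (self.pos - 1, self.pos)
        return (self.pos - 1, self.end)


@dataclass
class SVCallSet:
    """All SV calls of one sample, sorted by (chrom, pos)."""

    sample_id: str
    records: list[SVRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.sample_id != self.sample_id:
                raise ConsistencyError(
                    f"record sample {rec.sample_id!r} != call set "
                    f"{self.sample_id!r}")
        self.records = sorted(self.records, key=lambda r: (r.chrom, r.pos))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sizes(self) -> np.ndarray:
        return np.array([r.svlen for r in self.records], dtype=int)


@dataclass
class SVCluster:
    """A cross-sample merged variant: single-linkage cluster of records whose
    breakpoints lie within the merge distance, with per-sample presence."""

    cluster_id: str
    chrom: str
    svtype: str
    rep_pos: int
    rep_end: int
    rep_len: int
    members: dict[str, list[SVRecord]] = field(default_factory=dict)
    presence: dict[str, bool] = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return sum(len(v) for v in self.members.values())


@dataclass(frozen=True)
class GeneModel:
    """A gene span with exon sub-intervals (1-based inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConsistencyError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ConsistencyError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        prev_end = None
        for (s, e) in self.exons:
            if s > e or s < self.start or e > self.end:
                raise ConsistencyError(
                    f"gene {self.gene_id}: exon {s}..{e} outside span")
            if prev_end is not None and s <= prev_end:
                raise ConsistencyError(
                    f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e


@dataclass
class GenomeLayout:
    """Ordered chromosomes with lengths and subgenome labels.

    Subgenome is inferred from the name prefix (A* -> A, C* -> C) unless an
    explicit label is given, matching the A/C subgenome nomenclature of
    allopolyploid Brassica.
    """

    chromosomes: list[tuple[str, int, str]]

    def __init__(self,
                 chromosomes: Iterable[tuple[str, int] | tuple[str, int, str]]):
        out: list[tuple[str, int, str]] = []
        seen: set[str] = set()
        for entry in chromosomes:
            if len(entry) == 2:
                name, length = entry  # type: ignore[misc]
                label = self._infer_subgenome(name)
            else:
                name, length, label = entry  # type: ignore[misc]
            if length <= 0:
                raise ConsistencyError(f"chromosome {name}: length {length} <= 0")
            if name in seen:
                raise ConsistencyError(f"duplicate chromosome name {name!r}")
            seen.add(name)
            out.append((str(name), int(length), label))
        self.chromosomes = out

    @staticmethod
    def _infer_subgenome(name: str) -> str:
        if name.upper().startswith("A"):
            return "A"
        if name.upper().startswith("C"):
            return "C"
        return "other"

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    def length(self, chrom: str) -> int:
        for name, length, _ in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def subgenome(self, chrom: str) -> str:
        for name, _, label in self.chromosomes:
            if name == chrom:
                return label
        raise KeyError(chrom)

    def subgenome_chroms(self, label: str) -> list[str]:
        return [c for c, _, lab in self.chromosomes if lab == label]

    @classmethod
    def from_tsv(cls, path) -> "GenomeLayout":
        """Read a two-column chromosome-sizes table (name, length)."""
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(f"bad chrom-sizes line: {line!r}")
                rows.append((parts[0], int(parts[1])))
        if not rows:
            raise FormatError(f"empty chromosome sizes file: {path}")
        return cls(rows)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name, length, _ in self.chromosomes:
                fh.write(f"{name}\t{length}\n")


@dataclass
class DepthBlock:
    """Median read depth of one fixed-width tile of a chromosome."""

    chrom: str
    block_index: int
    start: int          # 1-based
    width: int
    median_depth: float


@dataclass
class CNVSegment:
    """Maximal run of adjacent depth blocks above the duplication threshold."""

    chrom: str
    start: int
    end: int
    n_blocks: int
    mean_block_depth: float
    call: str = "duplication"


@dataclass
class SVMatrix:
    """Samples x merged-SV binary presence/absence matrix."""

    samples: list[str]
    cluster_ids: list[str]
    cells: np.ndarray  # shape (n_samples, n_clusters), dtype int8

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.samples), len(self.cluster_ids)):
            raise ConsistencyError(
                f"matrix shape {self.cells.shape} != "
                f"({len(self.samples)}, {len(self.cluster_ids)})")
        if len(set(self.samples)) != len(self.samples):
            raise ConsistencyError("duplicate sample ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    def invariant_columns(self) -> int:
        """Number of columns that are all-0 or all-1 (uninformative sites)."""
        if self.cells.shape[1] == 0:
            return 0
        colsum = self.cells.sum(axis=0)
        n = self.cells.shape[0]
        return int(np.sum((colsum == 0) | (colsum == n)))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded to ``ndigits`` decimals; denominator must be > 0."""
    if denominator <= 0:
        raise ValueError("percentage undefined for non-positive denominator")
    return round(100.0 * numerator / denominator, ndigits)
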