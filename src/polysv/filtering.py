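"""Stringent quality filtering and size accounting of SV calls.

The default policy reproduces the study design for small- to mid-scale SV in
a polyploid genome whose reference assembly cannot yet support confident
calling of large or complex events:

* drop all translocations and duplications,
* keep only calls the caller scored PASS (UNRESOLVED discarded),
* require within-alignment (AL) read support,
* restrict to the studied size range 30 bp .. 30 kb.

Size classes split that range into "small" (30 bp .. 10 kb, inclusive) and
"mid" (10 kb exclusive .. 30 kb inclusive) so the classes partition it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import SVCallSet, SVRecord, percent


@dataclass(frozen=True)
class FilterPolicy:
    drop_types: frozenset[str] = frozenset({"TRA", "DUP"})
    require_filter: str = "PASS"
    require_support: str = "AL"
    min_size: int | None = 30
    max_size: int | None = 30_000

    def __post_init__(self) -> None:
        if self.min_size is not None and self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if (self.min_size is not None and self.max_size is not None
                and self.max_size <= self.min_size):
            raise ValueError("max_size must exceed min_size")

    def keeps(self, rec: SVRecord) -> bool:
        """Pointwise predicate: does this record survive the filter?"""
        if rec.svtype in self.drop_types:
            return False
        if rec.filter_status != self.require_filter:
            return False
        if self.require_support and self.require_support not in rec.support_types:
            return False
        if self.min_size is not None and rec.svlen < self.min_size:
            return False
        if self.max_size is not None and rec.svlen > self.max_size:
            return False
        return True


def quality_filter(callset: SVCallSet,
                   policy: FilterPolicy = FilterPolicy()) -> SVCallSet:
    """Retain exactly the records passing the policy predicate, in order."""
    kept = [r for r in callset if policy.keeps(r)]
    return SVCallSet(sample_id=callset.sample_id, records=kept,
                     provenance=callset.provenance)


SMALL_MAX = 10_000
MID_MAX = 30_000


def size_class(svlen: int) -> str:
    """Classify an SV size as 'small' (30..10 000), 'mid' (10 001..30 000)
    or 'out_of_range'."""
    if svlen <= 0:
        raise ValueError(f"svlen must be positive, got {svlen}")
    if 30 <= svlen <= SMALL_MAX:
        return "small"
    if SMALL_MAX < svlen <= MID_MAX:
        return "mid"
    return "out_of_range"


@dataclass
class CallSetSummary:
    """Per-sample summary mirroring the per-genotype SV accounting table."""

    sample_id: str
    n_sv: int
    median_size: float | None
    max_size: int | None
    n_small: int = 0
    n_mid: int = 0
    frac_100_1000: float | None = None
    per_chrom: dict[str, int] = field(default_factory=dict)


def summarize(callset: SVCallSet) -> CallSetSummary:
    """Median/maximum size, size-class counts and the 100-1000 bp fraction.

    The median is the standard middle-order statistic (mean of the two
    central values for even n); the 100-1000 bp fraction uses inclusive
    bounds. An empty call set yields n_sv = 0 with size fields absent.
    """
    sizes = callset.sizes()
    per_chrom: dict[str, int] = {}
    for rec in callset:
        per_chrom[rec.chrom] = per_chrom.get(rec.chrom, 0) + 1
    if len(sizes) == 0:
        return CallSetSummary(callset.sample_id, 0, None, None,
                              per_chrom=per_chrom)
    labels = [size_class(int(s)) for s in sizes]
    in_band = int(np.sum((sizes >= 100) & (sizes <= 1000)))
    return CallSetSummary(
        sample_id=callset.sample_id,
        n_sv=len(sizes),
        median_size=float(np.median(sizes)),
        max_size=int(sizes.max()),
        n_small=labels.count("small"),
        n_mid=labels.count("mid"),
        frac_100_1000=in_band / len(sizes),
        per_chrom=per_chrom,
    )
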