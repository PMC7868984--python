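"""Read-depth CNV detection by block medians and per-chromosome thresholds.

The procedure summarizes per-base coverage into medians of fixed 1 kb tiles,
computes the median and standard deviation of those block medians per
chromosome, and flags blocks whose median exceeds
``chromosome median + k * chromosome sd`` (k = 1 by default) as duplicated;
maximal runs of adjacent flagged blocks become CNV segments. A deletion-side
call (below ``median - k*sd``) is available behind the ``direction``
argument but is off by default. Whole-chromosome loss is flagged separately:
a chromosome whose median block depth falls below a fraction (default 0.1)
of the genome-wide median block depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import CNVSegment, DepthBlock, FormatError

DEFAULT_BLOCK_WIDTH = 1000


@dataclass
class DepthTrack:
    """Per-base read depth of one chromosome (index 0 = position 1)."""

    chrom: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")
        if self.depth.size and self.depth.min() < 0:
            raise ValueError("depth must be non-negative")

    def __len__(self) -> int:
        return int(self.depth.size)


def read_bedgraph(path) -> dict[str, DepthTrack]:
    """Expand a bedGraph (0-based half-open chrom/start/end/depth) into
    per-base depth tracks, one per chromosome.

    Intervals of each chromosome must tile it contiguously from 0.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "depth"],
                     dtype={"chrom": str})
    if df.empty:
        raise FormatError(f"empty bedGraph: {path}")
    tracks: dict[str, DepthTrack] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if starts[0] != 0 or np.any(starts[1:] != ends[:-1]):
            raise FormatError(
                f"{path}: intervals of {chrom} do not tile contiguously")
        depth = np.repeat(sub["depth"].to_numpy(), ends - starts)
        tracks[str(chrom)] = DepthTrack(chrom=str(chrom), depth=depth)
    return tracks


def write_bedgraph(tracks: Mapping[str, DepthTrack], path) -> None:
    """Run-length-encode per-base tracks into bedGraph text."""
    with open(path, "w") as fh:
        for chrom in tracks:
            depth = tracks[chrom].depth
            if depth.size == 0:
                continue
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [depth.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{depth[s]:g}\n")


def block_medians(track: DepthTrack,
                  width: int = DEFAULT_BLOCK_WIDTH) -> list[DepthBlock]:
    """Median per-base depth over fixed-width tiles (final tile truncated)."""
    if len(track) == 0:
        raise ValueError(f"empty depth track for {track.chrom}")
    if width < 1:
        raise ValueError("block width must be >= 1")
    depth = track.depth.astype(float)
    n_full = depth.size // width
    blocks: list[DepthBlock] = []
    if n_full:
        med = np.median(depth[:n_full * width].reshape(n_full, width), axis=1)
        for i in range(n_full):
            blocks.append(DepthBlock(track.chrom, i, i * width + 1, width,
                                     float(med[i])))
    rest = depth[n_full * width:]
    if rest.size:
        blocks.append(DepthBlock(track.chrom, n_full, n_full * width + 1,
                                 int(rest.size), float(np.median(rest))))
    return blocks


@dataclass
class ChromosomeStats:
    chrom: str
    median: float
    sd: float
    n_blocks: int


def chromosome_stats(blocks: Sequence[DepthBlock]) -> ChromosomeStats:
    """Median and population standard deviation of one chromosome's block
    medians."""
    if len(blocks) < 2:
        raise ValueError("need at least two blocks for chromosome stats")
    chroms = {b.chrom for b in blocks}
    if len(chroms) != 1:
        raise ValueError(f"blocks span several chromosomes: {sorted(chroms)}")
    values = np.array([b.median_depth for b in blocks])
    return ChromosomeStats(chrom=blocks[0].chrom,
                           median=float(np.median(values)),
                           sd=float(np.std(values)),
                           n_blocks=len(blocks))


def call_duplications(blocks: Sequence[DepthBlock], stats: ChromosomeStats,
                      k: float = 1.0,
                      direction: str = "gain") -> list[CNVSegment]:
    """Merge maximal runs of blocks beyond ``median +/- k*sd`` into segments.

    ``direction="gain"`` (default) calls duplications above
    ``median + k*sd``; ``direction="loss"`` calls depth drops below
    ``median - k*sd``. A zero sd degenerates to a strict comparison with
    the median.
    """
    if direction not in ("gain", "loss"):
        raise ValueError(f"direction must be gain or loss, got {direction!r}")
    if blocks and blocks[0].chrom != stats.chrom:
        raise ValueError(
            f"blocks are {blocks[0].chrom} but stats are {stats.chrom}")
    if direction == "gain":
        threshold = stats.median + k * stats.sd
        flagged = [b.median_depth > threshold for b in blocks]
        call = "duplication"
    else:
        threshold = stats.median - k * stats.sd
        flagged = [b.median_depth < threshold for b in blocks]
        call = "loss"
    segments: list[CNVSegment] = []
    run: list[DepthBlock] = []
    prev_index = None
    for b, f in zip(blocks, flagged):
        adjacent = prev_index is not None and b.block_index == prev_index + 1
        if f:
            if run and not adjacent:
                segments.append(_segment(run, call))
                run = []
            run.append(b)
            prev_index = b.block_index
        else:
            if run:
                segments.append(_segment(run, call))
                run = []
            prev_index = b.block_index
    if run:
        segments.append(_segment(run, call))
    return segments


def _segment(run: list[DepthBlock], call: str) -> CNVSegment:
    return CNVSegment(
        chrom=run[0].chrom,
        start=run[0].start,
        end=run[-1].start + run[-1].width - 1,
        n_blocks=len(run),
        mean_block_depth=float(np.mean([b.median_depth for b in run])),
        call=call,
    )


def detect_chromosome_loss(blocks_by_chrom: Mapping[str, Sequence[DepthBlock]],
                           loss_fraction: float = 0.1) -> list[str]:
    """Chromosomes whose median block depth is below ``loss_fraction`` of
    the genome-wide median block depth.

    Formalizes whole-chromosome absence (e.g. a chromosome replaced by its
    homoeolog) as a testable read-depth criterion.
    """
    if len(blocks_by_chrom) < 2:
        raise ValueError("need at least two chromosomes")
    all_medians = np.concatenate([
        [b.median_depth for b in blocks]
        for blocks in blocks_by_chrom.values()])
    genome_median = float(np.median(all_medians))
    flagged = []
    for chrom, blocks in blocks_by_chrom.items():
        med = float(np.median([b.median_depth for b in blocks]))
        if med < loss_fraction * genome_median:
            flagged.append(chrom)
    return flagged


def segments_to_bed(segments: Iterable[CNVSegment], path) -> None:
    """Write CNV segments as BED (0-based half-open) with depth in column 5."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\t{seg.call}"
                     f"\t{seg.mean_block_depth:.2f}\n")
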