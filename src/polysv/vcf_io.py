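"""Reading and writing the Sniffles-style structural-variant VCF dialect.

The dialect is VCF 4.2 with symbolic ALT alleles and the INFO keys SVTYPE,
SVLEN (signed; negative for deletions), END, RE (supporting reads) and
SUPTYPE (comma list from {AL, SR, NR}), plus a PRECISE/IMPRECISE flag.
FILTER is PASS or UNRESOLVED. Single-sample files are sites-only; the
multi-sample export adds a GT column per sample (1/1 present, 0/0 absent).

Parsing goes through :mod:`pysam`; writing emits the dialect as text so the
round trip is exact.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import pysam

from .model import (
    ConsistencyError,
    FormatError,
    GenomeLayout,
    MalformedRecordError,
    SVCallSet,
    SVCluster,
    SVRecord,
)

log = logging.getLogger(__name__)

_HEADER_LINES = [
    '##fileformat=VCFv4.2',
    '##source=polysv',
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the SV (negative for deletions)">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the SV">',
    '##INFO=<ID=RE,Number=1,Type=Integer,Description="Number of reads supporting the SV">',
    '##INFO=<ID=SUPTYPE,Number=.,Type=String,Description="Type of support for the SV (AL, SR, NR)">',
    '##INFO=<ID=PRECISE,Number=0,Type=Flag,Description="Breakpoints are precise">',
    '##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Breakpoints are imprecise">',
    '##FILTER=<ID=UNRESOLVED,Description="SV could not be resolved confidently">',
    '##ALT=<ID=DEL,Description="Deletion">',
    '##ALT=<ID=INS,Description="Insertion">',
    '##ALT=<ID=INV,Description="Inversion">',
    '##ALT=<ID=DUP,Description="Duplication">',
    '##ALT=<ID=TRA,Description="Translocation">',
]


def _info_field(rec: SVRecord) -> str:
    svlen = -rec.svlen if rec.svtype == "DEL" else rec.svlen
    precision = "PRECISE" if rec.precise else "IMPRECISE"
    suptype = ",".join(s for s in ("AL", "SR", "NR") if s in rec.support_types)
    return (f"{precision};SVTYPE={rec.svtype};SVLEN={svlen};END={rec.end};"
            f"RE={rec.read_support};SUPTYPE={suptype}")


def _header(layout: GenomeLayout | None, samples: Sequence[str] | None) -> str:
    lines = list(_HEADER_LINES)
    if layout is not None:
        for name, length, _ in layout.chromosomes:
            lines.append(f'##contig=<ID={name},length={length}>')
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        cols += ["FORMAT", *samples]
    lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


def read_sniffles_vcf(path, sample_id: str) -> SVCallSet:
    """Read a single-sample SV VCF into a normalized, sorted call set.

    Negative SVLEN (deletions) is stored as a magnitude. Records missing
    SVTYPE raise :class:`MalformedRecordError` naming the offending line.
    Unknown INFO keys are ignored; FILTER values other than PASS/UNRESOLVED
    are mapped to UNRESOLVED with a warning.
    """
    verbosity = pysam.set_verbosity(0)  # silence undefined-contig chatter
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    finally:
        pysam.set_verbosity(verbosity)
    records: list[SVRecord] = []
    with vf:
        for i, rec in enumerate(vf, start=1):
            info = dict(rec.info)
            if "SVTYPE" not in info:
                raise MalformedRecordError(
                    f"{path}: data line {i} ({rec.chrom}:{rec.pos}) "
                    "lacks SVTYPE")
            svtype = str(info["SVTYPE"])
            if svtype not in ("DEL", "INS", "INV", "DUP", "TRA"):
                raise MalformedRecordError(
                    f"{path}: data line {i}: unknown SVTYPE {svtype!r}")
            svlen_raw = info.get("SVLEN")
            if isinstance(svlen_raw, tuple):
                svlen_raw = svlen_raw[0]
            if svlen_raw is None:
                if svtype != "TRA":
                    raise MalformedRecordError(
                        f"{path}: data line {i}: {svtype} lacks SVLEN")
                svlen = 1
            else:
                svlen = abs(int(svlen_raw))
            if svtype in ("INS", "TRA"):
                end = rec.pos
            else:
                # pysam folds the END INFO key into rec.stop; for spanning
                # types a stop at/below pos means END was absent.
                end = rec.stop
                if end <= rec.pos and svlen > 1:
                    raise MalformedRecordError(
                        f"{path}: data line {i}: {svtype} lacks END")
            filters = list(rec.filter.keys())
            status = filters[0] if filters else "PASS"
            if status == ".":
                status = "PASS"
            if status not in ("PASS", "UNRESOLVED"):
                log.warning("%s line %d: FILTER %r mapped to UNRESOLVED",
                            path, i, status)
                status = "UNRESOLVED"
            suptype = info.get("SUPTYPE")
            if suptype is None:
                support = frozenset({"SR"})
            else:
                if isinstance(suptype, str):
                    suptype = (suptype,)
                support = frozenset(
                    s for part in suptype for s in str(part).split(","))
            re_raw = info.get("RE", 0)
            if isinstance(re_raw, tuple):
                re_raw = re_raw[0]
            precise = bool(info.get("PRECISE", False)) or not bool(
                info.get("IMPRECISE", False))
            records.append(SVRecord(
                sample_id=sample_id,
                chrom=rec.chrom,
                pos=rec.pos,
                end=max(int(end), rec.pos),
                svtype=svtype,
                svlen=max(svlen, 1),
                filter_status=status,
                support_types=support,
                read_support=int(re_raw),
                precise=precise,
            ))
    return SVCallSet(sample_id=sample_id, records=records,
                     provenance=f"read from {path}")


def write_vcf(callset: SVCallSet, path, layout: GenomeLayout | None = None) -> None:
    """Write a call set in the single-sample dialect (sites-only columns)."""
    with open(path, "w") as fh:
        fh.write(_header(layout, None))
        for rec in callset:
            fh.write("\t".join([
                rec.chrom, str(rec.pos), ".", "N", f"<{rec.svtype}>", ".",
                rec.filter_status, _info_field(rec),
            ]) + "\n")


def write_multisample_vcf(clusters: Sequence[SVCluster],
                          samples: Sequence[str], path,
                          layout: GenomeLayout | None = None) -> None:
    """Write merged clusters as a multi-sample VCF with 1/1 / 0/0 genotypes."""
    samples = list(samples)
    for cl in clusters:
        if set(cl.presence) != set(samples):
            raise ConsistencyError(
                f"cluster {cl.cluster_id}: presence samples "
                f"{sorted(cl.presence)} != {sorted(samples)}")
    with open(path, "w") as fh:
        fh.write(_header(layout, samples))
        for cl in sorted(clusters, key=lambda c: (c.chrom, c.rep_pos)):
            svlen = -cl.rep_len if cl.svtype == "DEL" else cl.rep_len
            info = (f"SVTYPE={cl.svtype};SVLEN={svlen};END={cl.rep_end};"
                    f"RE={cl.n_members};SUPTYPE=AL")
            gts = ["1/1" if cl.presence[s] else "0/0" for s in samples]
            fh.write("\t".join([
                cl.chrom, str(cl.rep_pos), cl.cluster_id, "N",
                f"<{cl.svtype}>", ".", "PASS", info, "GT", *gts,
            ]) + "\n")


def read_multisample_vcf(path) -> tuple[list[str], list[str], list[list[bool]]]:
    """Read a multi-sample presence VCF.

    Returns (samples, cluster ids, presence rows) where presence rows are
    indexed [cluster][sample] in file order.
    """
    verbosity = pysam.set_verbosity(0)  # silence undefined-contig chatter
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    finally:
        pysam.set_verbosity(verbosity)
    with vf:
        samples = list(vf.header.samples)
        ids: list[str] = []
        rows: list[list[bool]] = []
        for rec in vf:
            ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            row = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                row.append(bool(gt) and all(a == 1 for a in gt if a is not None)
                           and any(a is not None for a in gt))
            rows.append(row)
    return samples, ids, rows
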