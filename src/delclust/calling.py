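"""Support filtering, representative selection, and VCF output.

A candidate cluster's *support* is its number of member signatures (one per
read-level observation). Filtering is coverage-aware and two-case:

* a large cluster that produced a **single** candidate cluster keeps it only
  if ``support >= min_support``;
* a large cluster that produced **two** candidate clusters (two deletion
  alleles) keeps each independently if ``support >= min_support / 2`` —
  each haplotype contributes only about half the reads, so holding both
  alleles to the full threshold would discard real heterozygous deletions.

``min_support`` scales with sequencing depth; the conventional presets are
10/5/3/2/2 for ~69X/35X/20X/10X/5X noisy (CLR) long reads and 3/2/1 for
28X/10X/5X HiFi (CCS) reads.

The surviving cluster is reported as the member closest (L1 distance in
position-length space) to the cluster's mean position and mean length, so
every emitted breakpoint is one actually observed in a read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .clustering import CandidateCluster

logger = logging.getLogger("delclust")

try:  # pyfaidx only needed when a reference FASTA is supplied
    from pyfaidx import Fasta
except ImportError:  # pragma: no cover
    Fasta = None


@dataclass(frozen=True)
class CallingConfig:
    """Support-filter settings.

    ``min_support`` defaults to 10 (deep noisy long-read data); lower it in
    step with coverage (presets above). ``unique_reads`` counts support as
    distinct read names instead of raw signatures.
    """

    min_support: int = 10
    unique_reads: bool = False

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


@dataclass(frozen=True)
class DeletionCall:
    """Final output record for one deletion."""

    chrom: str
    start: int  # 0-based first deleted base
    svlen: int
    end: int  # start + svlen
    support: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.end != self.start + self.svlen:
            raise ValueError("end must equal start + svlen")
        if self.support < 1:
            raise ValueError("support must be >= 1")


def support_of(cc: CandidateCluster, cfg: CallingConfig | None = None) -> int:
    """Number of member signatures (or distinct reads with ``unique_reads``)."""
    if cfg is not None and cfg.unique_reads:
        return len({m.read_name for m in cc.members})
    return len(cc.members)


def filter_candidates(
    candidates: list[CandidateCluster], cfg: CallingConfig
) -> list[CandidateCluster]:
    """Two-case support filter for one large cluster's candidate clusters.

    One candidate: kept iff support >= ``min_support``. Two candidates:
    each kept independently iff support >= ``min_support / 2`` (real-valued
    half, no rounding).
    """
    if len(candidates) not in (1, 2):
        raise ValueError("a large cluster yields one or two candidate clusters")
    threshold = cfg.min_support if len(candidates) == 1 else cfg.min_support / 2
    return [cc for cc in candidates if support_of(cc, cfg) >= threshold]


def select_representative(cc: CandidateCluster, call_id: str = "") -> DeletionCall:
    """Call the member closest to the cluster mean in (start, svlen) L1 distance.

    Ties break by smaller start, then smaller svlen, then read name.
    """
    mean_start = cc.mean_start
    mean_len = cc.mean_len
    winner = min(
        cc.members,
        key=lambda m: (
            abs(m.start - mean_start) + abs(m.svlen - mean_len),
            m.start,
            m.svlen,
            m.read_name,
        ),
    )
    return DeletionCall(
        chrom=winner.chrom,
        start=winner.start,
        svlen=winner.svlen,
        end=winner.start + winner.svlen,
        support=len(cc.members),
        id=call_id,
    )


def make_calls(
    candidate_groups: list[list[CandidateCluster]], cfg: CallingConfig
) -> list[DeletionCall]:
    """Filter every large cluster's candidates and call the survivors."""
    calls: list[DeletionCall] = []
    for group in candidate_groups:
        for cc in filter_candidates(group, cfg):
            calls.append(select_representative(cc))
    calls.sort(key=lambda c: (c.chrom, c.start, c.svlen))
    return [
        DeletionCall(
            chrom=c.chrom, start=c.start, svlen=c.svlen, end=c.end,
            support=c.support, id=f"DEL.{i}",
        )
        for i, c in enumerate(calls, start=1)
    ]


# ---------------------------------------------------------------------------
# VCF output

_VCF_META = """\
##fileformat=VCFv4.2
##source=delclust
##ALT=<ID=DEL,Description="Deletion">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant (negative for deletions)">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Number of supporting signatures">
##FILTER=<ID=PASS,Description="All filters passed">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(
    calls: list[DeletionCall],
    out_path: str,
    chrom_lengths: dict[str, int] | None = None,
    reference: str | None = None,
    sample: str = "SAMPLE",
) -> None:
    """Write deletion calls as a VCF 4.2 file.

    POS is the 1-based anchor base *before* the deletion (so a 0-based
    deletion start ``s`` becomes POS ``s``); REF is the anchor base from
    the reference FASTA, or ``N`` when no reference is given; ALT is the
    symbolic ``<DEL>``. END is the 1-based inclusive end of the deleted
    segment (POS + svlen). No genotype is inferred; a ``./.`` placeholder
    sample column is written for downstream-tool compatibility.
    """
    for a, b in zip(calls, calls[1:]):
        if (a.chrom, a.start) > (b.chrom, b.start):
            raise ValueError("calls must be sorted by (chrom, start)")
    fasta = None
    if reference is not None:
        if Fasta is None:  # pragma: no cover
            raise RuntimeError("pyfaidx is required to read the reference FASTA")
        fasta = Fasta(reference)
    with open(out_path, "w") as fh:
        fh.write(_VCF_META)
        for chrom, length in (chrom_lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample}\n"
        )
        for call in calls:
            pos = call.start  # 1-based anchor base == 0-based deletion start
            ref = "N"
            if pos < 1:
                pos = 1
            elif fasta is not None:
                if call.chrom in fasta:
                    ref = str(fasta[call.chrom][pos - 1 : pos]).upper() or "N"
                else:
                    logger.warning(
                        "chromosome %s absent from reference; REF set to N",
                        call.chrom,
                    )
            info = (
                f"SVTYPE=DEL;SVLEN={-call.svlen};END={pos + call.svlen};"
                f"SUPPORT={call.support}"
            )
            fh.write(
                f"{call.chrom}\t{pos}\t{call.id or '.'}\t{ref}\t<DEL>\t.\tPASS\t"
                f"{info}\tGT\t./.\n"
            )
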