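"""Deletion-signature extraction from long-read alignments.

A deletion leaves one of two footprints in a read-to-reference alignment:

* **intra-read** — a ``D`` run in the CIGAR string of a single alignment
  record (small deletions the aligner can bridge);
* **inter-read** — the read is split into two alignment records (primary +
  supplementary) that land on non-adjacent loci of the same chromosome on
  the same strand; the reference gap between them, corrected for any gap on
  the read, is the implied deletion length.

This module reads a BAM/SAM file, applies the mapping-quality filter,
extracts both evidence classes per read, merges sequencing-error-fragmented
CIGAR deletions, and returns per-chromosome lists of
:class:`DeletionSignature`.

All coordinates are 0-based, half-open. The SAM/BAM reader (pysam) already
provides 0-based positions; the VCF writer converts back to 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import pysam

logger = logging.getLogger("delclust")

# CIGAR operation alphabet. Reference-consuming ops advance the reference
# cursor; query-consuming ops advance the read cursor.
_REF_OPS = frozenset("MDN=X")
_QUERY_OPS = frozenset("MIS=X")
_KNOWN_OPS = frozenset("MIDNSH=X")
_PYSAM_OP = "MIDNSHP=XB"  # pysam integer op codes -> characters


@dataclass(frozen=True)
class ExtractionConfig:
    """Thresholds governing signature extraction.

    Parameters
    ----------
    min_mapq
        Alignment records with MAPQ below this are discarded (default 20).
    min_cigar_del
        Only CIGAR ``D`` runs strictly longer than this are deletion
        evidence (default 30 bp).
    max_merge_gap
        Two same-read CIGAR deletions separated by a gap ``g`` with
        ``0 < g <= max_merge_gap`` are merged into one (default 30 bp);
        this repairs deletions fragmented by sequencing error.
    min_split_del, max_split_del
        Inclusive bounds on the split-read ``Distance`` for it to count as
        a deletion (defaults 50 and 100 000 bp).
    """

    min_mapq: int = 20
    min_cigar_del: int = 30
    max_merge_gap: int = 30
    min_split_del: int = 50
    max_split_del: int = 100_000

    def __post_init__(self) -> None:
        if self.min_split_del >= self.max_split_del:
            raise ValueError("min_split_del must be < max_split_del")
        for name in ("min_mapq", "min_cigar_del", "max_merge_gap",
                     "min_split_del", "max_split_del"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class AlignmentRecord:
    """The slice of a SAM record the caller needs; no sequence retained."""

    read_name: str
    chrom: str
    ref_start: int
    mapq: int
    cigar: tuple[tuple[str, int], ...]
    orient: str  # '+' or '-'
    is_supplementary: bool = False
    is_unmapped: bool = False


@dataclass(frozen=True, order=True)
class DeletionSignature:
    """One read's evidence for one deletion.

    ``svlen`` is the deletion length used by all downstream steps. ``end``
    is the reference span end; for plain CIGAR deletions it equals
    ``start + svlen``, but for merged fragmented deletions it is the second
    constituent's end, and for split-read deletions it is the second
    segment's reference start — in both cases the intervening gap bases are
    not counted in ``svlen``.
    """

    chrom: str
    start: int
    svlen: int
    end: int
    read_name: str
    source: str = "cigar"  # 'cigar' | 'split'

    def __post_init__(self) -> None:
        if self.svlen <= 0:
            raise ValueError("svlen must be positive")


@dataclass(frozen=True)
class SplitSegment:
    """One aligned segment of a split read.

    ``read_start``/``read_end`` are half-open offsets on the read in its
    *original* orientation (reverse-strand records are flipped using the
    full read length), so sorting by ``read_start`` recovers the order the
    segments occur along the read.
    """

    chrom: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    orient: str
    read_name: str

    def __post_init__(self) -> None:
        if self.ref_end <= self.ref_start:
            raise ValueError("ref_end must exceed ref_start")
        if self.read_end <= self.read_start:
            raise ValueError("read_end must exceed read_start")


# ---------------------------------------------------------------------------
# Alignment-file reading


def _record_from_pysam(aln: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = tuple((_PYSAM_OP[op], length) for op, length in (aln.cigartuples or ()))
    return AlignmentRecord(
        read_name=aln.query_name,
        chrom=aln.reference_name,
        ref_start=aln.reference_start,
        mapq=aln.mapping_quality,
        cigar=cigar,
        orient="-" if aln.is_reverse else "+",
        is_supplementary=aln.is_supplementary,
        is_unmapped=aln.is_unmapped,
    )


def read_alignments(
    path: str,
    cfg: ExtractionConfig,
    region: str | None = None,
) -> Iterator[list[AlignmentRecord]]:
    """Stream alignment records grouped by read name.

    Unmapped records, secondary alignments, and records with
    ``MAPQ < cfg.min_mapq`` are dropped. Primary and supplementary records
    of one read are yielded together (supplementaries carry the split-read
    evidence). Groups are yielded in sorted read-name order so downstream
    output never depends on file record order.
    """
    try:
        af = pysam.AlignmentFile(path, require_index=False)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot open alignment file {path!r}: {exc}") from exc
    with af:
        if region is not None and not af.has_index():
            raise OSError(
                f"region query {region!r} requires an index "
                f"({path}.bai / .csi); none found"
            )
        source = af.fetch(region=region) if region else af
        groups: dict[str, list[AlignmentRecord]] = {}
        for aln in source:
            if aln.is_unmapped or aln.is_secondary:
                continue
            if aln.mapping_quality < cfg.min_mapq:
                continue
            groups.setdefault(aln.query_name, []).append(_record_from_pysam(aln))
    for name in sorted(groups):
        yield groups[name]


def chromosome_lengths(path: str) -> dict[str, int]:
    """Contig name -> length map from the alignment-file header."""
    with pysam.AlignmentFile(path, require_index=False) as af:
        return dict(zip(af.references, af.lengths))


# ---------------------------------------------------------------------------
# Intra-read (CIGAR) evidence


def extract_cigar_signatures(
    rec: AlignmentRecord, cfg: ExtractionConfig
) -> list[DeletionSignature]:
    """Signatures from CIGAR ``D`` runs strictly longer than ``min_cigar_del``.

    The deletion start is the record's reference start plus the reference
    length consumed by the preceding operations; a malformed CIGAR (unknown
    op) skips the record with a warning.
    """
    for op, _ in rec.cigar:
        if op not in _KNOWN_OPS:
            logger.warning(
                "read %s: unknown CIGAR op %r — record skipped", rec.read_name, op
            )
            return []
    out: list[DeletionSignature] = []
    ref_pos = rec.ref_start
    for op, length in rec.cigar:
        if op == "D" and length > cfg.min_cigar_del:
            out.append(
                DeletionSignature(
                    chrom=rec.chrom,
                    start=ref_pos,
                    svlen=length,
                    end=ref_pos + length,
                    read_name=rec.read_name,
                    source="cigar",
                )
            )
        if op in _REF_OPS:
            ref_pos += length
    return out


def merge_intra_read(
    sigs: list[DeletionSignature], cfg: ExtractionConfig
) -> list[DeletionSignature]:
    """Merge same-read deletions separated by a small alignment gap.

    For adjacent signatures the gap is ``start2 - end1``; a pair with
    ``0 < gap <= max_merge_gap`` becomes ``(start1, svlen1+svlen2, end2)``
    — the gap bases are not added to ``svlen``. A merged signature is
    immediately eligible for merging with the next (left-to-right cascade).
    Pairs with ``gap <= 0`` (overlap/abutment) or too-large gaps are kept
    apart.
    """
    if any(sigs[i].start > sigs[i + 1].start for i in range(len(sigs) - 1)):
        raise ValueError("merge_intra_read requires input sorted by start")
    if not sigs:
        return []
    merged = [sigs[0]]
    for sig in sigs[1:]:
        prev = merged[-1]
        gap = sig.start - prev.end
        if 0 < gap <= cfg.max_merge_gap:
            merged[-1] = replace(
                prev, svlen=prev.svlen + sig.svlen, end=sig.end
            )
        else:
            merged.append(sig)
    return merged


# ---------------------------------------------------------------------------
# Inter-read (split-alignment) evidence


def _query_span(cigar: tuple[tuple[str, int], ...]) -> tuple[int, int, int]:
    """(aligned start, aligned end, full read length) in alignment orientation.

    Clips (S/H) flank the aligned part; the full read length includes them.
    """
    lead = 0
    i = 0
    while i < len(cigar) and cigar[i][0] in "SH":
        lead += cigar[i][1]
        i += 1
    aligned = sum(length for op, length in cigar if op in "MI=X")
    read_len = sum(length for op, length in cigar if op in "MISH=X")
    return lead, lead + aligned, read_len


def split_segment_from_record(rec: AlignmentRecord) -> SplitSegment:
    """Project an alignment record to a read-orientation split segment."""
    start_f, end_f, read_len = _query_span(rec.cigar)
    ref_len = sum(length for op, length in rec.cigar if op in _REF_OPS)
    if rec.orient == "-":
        read_start, read_end = read_len - end_f, read_len - start_f
    else:
        read_start, read_end = start_f, end_f
    return SplitSegment(
        chrom=rec.chrom,
        ref_start=rec.ref_start,
        ref_end=rec.ref_start + ref_len,
        read_start=read_start,
        read_end=read_end,
        orient=rec.orient,
        read_name=rec.read_name,
    )


def segments_from_sa_tag(
    primary: AlignmentRecord, sa: str, cfg: ExtractionConfig
) -> list[SplitSegment]:
    """Split segments recovered from a primary record's ``SA`` tag.

    Used when supplementary records are absent from the file. Each SA entry
    is ``rname,pos,strand,CIGAR,mapQ,NM;`` with a 1-based pos; entries below
    the MAPQ threshold are dropped, mirroring the per-record filter.
    """
    segments = [split_segment_from_record(primary)]
    for entry in sa.rstrip(";").split(";"):
        if not entry:
            continue
        rname, pos, strand, cig, mapq, _nm = entry.split(",")
        if int(mapq) < cfg.min_mapq:
            continue
        cigar = _parse_cigar(cig)
        rec = AlignmentRecord(
            read_name=primary.read_name,
            chrom=rname,
            ref_start=int(pos) - 1,
            mapq=int(mapq),
            cigar=cigar,
            orient=strand,
            is_supplementary=True,
        )
        segments.append(split_segment_from_record(rec))
    return segments


def _parse_cigar(text: str) -> tuple[tuple[str, int], ...]:
    out: list[tuple[str, int]] = []
    num = ""
    for ch in text:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return tuple(out)


def extract_split_signatures(
    segments: list[SplitSegment], cfg: ExtractionConfig
) -> list[DeletionSignature]:
    """Signatures implied by consecutive segments of one split read.

    For each read-adjacent pair on the same chromosome and strand::

        Distance_ref  = Ref_2s - Ref_1e
        Distance_read = Read_2s - Read_1e
        Distance      = Distance_ref - Distance_read

    If ``min_split_del <= Distance <= max_split_del`` the pair implies a
    deletion ``(chrom, Ref_1e, Distance, Ref_2s)``. Pairs failing the
    chromosome, orientation, or Distance gates emit nothing.

    For reverse-strand pairs, read order descends along the reference, so
    the reference gap is taken between the reference-ordered pair while the
    read gap stays in read order; for forward pairs this reduces exactly to
    the formula above.
    """
    segs = sorted(segments, key=lambda s: (s.read_start, s.read_end))
    out: list[DeletionSignature] = []
    for a, b in zip(segs, segs[1:]):
        if a.chrom != b.chrom or a.orient != b.orient:
            continue
        first, second = (a, b) if a.ref_start <= b.ref_start else (b, a)
        distance_ref = second.ref_start - first.ref_end
        distance_read = b.read_start - a.read_end
        distance = distance_ref - distance_read
        if cfg.min_split_del <= distance <= cfg.max_split_del:
            out.append(
                DeletionSignature(
                    chrom=first.chrom,
                    start=first.ref_end,
                    svlen=distance,
                    end=second.ref_start,
                    read_name=first.read_name,
                    source="split",
                )
            )
    return out


# ---------------------------------------------------------------------------
# Composition


def signatures_for_read(
    records: list[AlignmentRecord], cfg: ExtractionConfig
) -> list[DeletionSignature]:
    """All merged signatures for one read's record group."""
    out: list[DeletionSignature] = []
    by_chrom: dict[str, list[DeletionSignature]] = {}
    for rec in records:
        for sig in extract_cigar_signatures(rec, cfg):
            by_chrom.setdefault(sig.chrom, []).append(sig)
    for chrom_sigs in by_chrom.values():
        chrom_sigs.sort(key=lambda s: (s.start, s.end))
        out.extend(merge_intra_read(chrom_sigs, cfg))
    if len(records) > 1:
        segments = [split_segment_from_record(r) for r in records]
        out.extend(extract_split_signatures(segments, cfg))
    return out


def collect_signatures(
    path: str,
    cfg: ExtractionConfig,
    region: str | None = None,
) -> dict[str, list[DeletionSignature]]:
    """Extract, merge, and pool signatures from an alignment file.

    Returns a per-chromosome map; each list is sorted by
    ``(start, svlen, read_name)``, making the output independent of the
    file's record order.
    """
    per_chrom: dict[str, list[DeletionSignature]] = {}
    for group in read_alignments(path, cfg, region=region):
        for sig in signatures_for_read(group, cfg):
            per_chrom.setdefault(sig.chrom, []).append(sig)
    for sigs in per_chrom.values():
        sigs.sort(key=lambda s: (s.start, s.svlen, s.read_name))
    return dict(sorted(per_chrom.items()))
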