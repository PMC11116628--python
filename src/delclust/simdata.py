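"""Synthetic long-read alignment fixtures with implanted deletions.

The generator builds, from a single seed, a random reference, a truth set
of implanted deletions (homozygous or heterozygous with two allele
lengths), and alignment records constructed *directly* from the known
implants — no external aligner — so the whole caller can be exercised
hermetically and deterministically. The records reproduce the three
evidence classes a real aligner produces for deletions in kb-scale reads:

* small deletions appear as a single CIGAR ``D`` run in a spanning read;
* with probability ``frag_prob`` that run is fragmented into two ``D`` runs
  separated by a small spurious match, emulating sequencing-error-driven
  realignment;
* deletions of ``split_rep_threshold`` and above are emitted as a primary +
  supplementary same-strand record pair with ``SA`` tags, whose implied
  split Distance equals the implanted length.

Reads tile each of the two haplotypes at half the requested coverage with
interleaved phases, so a heterozygous locus sees both alleles in
alternating reads. Alternating reads are flagged reverse-strand (stored
sequence and CIGAR are identical; only the flag and the read-orientation
bookkeeping differ), exercising the strand handling of the extractor.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pysam
from pyfaidx import Faidx

from .calling import DeletionCall, write_vcf

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_BANDS: tuple[tuple[int, int], ...] = (
    (50, 200), (200, 500), (500, 1000), (1000, 2000), (2000, 10000),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults emulate a deep noisy long-read run: 8 kb reads (the average
    length of the benchmark CLR data this mirrors is ~7.9 kb), 20-fold
    total coverage split evenly over two haplotypes, and deletion lengths
    drawn round-robin from the five standard length bands. ``frag_gap`` is
    the spurious-match length inserted when a deletion is fragmented.
    """

    seed: int = 1
    n_chroms: int = 1
    chrom_length: int = 2_000_000
    n_deletions: int = 20
    length_bands: tuple[tuple[int, int], ...] = DEFAULT_BANDS
    coverage: float = 20.0
    read_length: int = 8000
    frag_prob: float = 0.0
    frag_gap: int = 10
    het_frac: float = 0.0
    split_rep_threshold: int = 2000
    noise: float = 0.0  # fraction of reads duplicated at sub-threshold MAPQ
    min_spacing: int = 4500  # >= 3x the layer-1 window

    def __post_init__(self) -> None:
        bands = self.length_bands
        if any(b[0] >= b[1] for b in bands):
            raise ValueError("bands must be (lo, hi) with lo < hi")
        if any(bands[i][1] > bands[i + 1][0] for i in range(len(bands) - 1)):
            raise ValueError("bands must be sorted and non-overlapping")
        for p in (self.frag_prob, self.het_frac, self.noise):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """One implanted deletion locus; ``svlen_hap2 == 0`` means hap2 intact."""

    chrom: str
    start: int
    svlen_hap1: int
    svlen_hap2: int
    zygosity: str  # 'hom' | 'het_same' | 'het_difflen'

    def __post_init__(self) -> None:
        if self.svlen_hap1 <= 0:
            raise ValueError("svlen_hap1 must be positive")
        if self.zygosity == "het_difflen" and (
            self.svlen_hap2 <= 0 or self.svlen_hap2 == self.svlen_hap1
        ):
            raise ValueError("het_difflen requires two unequal positive lengths")

    def alleles(self) -> list[int]:
        """Distinct allele lengths carried at this locus."""
        if self.zygosity == "het_difflen":
            return [self.svlen_hap1, self.svlen_hap2]
        return [self.svlen_hap1]


def make_het_locus(cfg: SimConfig, chrom: str, start: int, len1: int, len2: int) -> TruthRecord:
    """Truth record for a heterozygous locus with two different allele lengths.

    The reads realising the locus come from :func:`simulate`'s two-haplotype
    tiling: haplotype phases are interleaved, so half the spanning reads
    carry ``len1`` and half ``len2``.
    """
    if len1 == len2:
        raise ValueError("heterozygous different-length locus needs len1 != len2")
    return TruthRecord(chrom=chrom, start=start, svlen_hap1=len1,
                       svlen_hap2=len2, zygosity="het_difflen")


def place_deletions(cfg: SimConfig, rng: np.random.Generator) -> list[TruthRecord]:
    """Deterministically place the truth set.

    Each chromosome is divided into equal slots between read-length margins;
    one deletion sits in each slot at a jittered offset, guaranteeing loci
    are separated by at least ``min_spacing`` plus a read length so no read
    spans two loci.
    """
    per_chrom = _split_counts(cfg.n_deletions, cfg.n_chroms)
    max_len = max(hi for _, hi in cfg.length_bands)
    truth: list[TruthRecord] = []
    band_idx = 0
    for ci, count in enumerate(per_chrom):
        if count == 0:
            continue
        chrom = f"chr{ci + 1}"
        margin = cfg.read_length
        usable = cfg.chrom_length - 2 * margin
        slot = usable // count if count else usable
        need = max_len + cfg.min_spacing + cfg.read_length
        if slot < need:
            raise ValueError(
                f"cannot place {count} deletions on a {cfg.chrom_length} bp "
                f"chromosome with {cfg.min_spacing} bp spacing; reduce "
                "n_deletions or enlarge chrom_length"
            )
        for k in range(count):
            lo, hi = cfg.length_bands[band_idx % len(cfg.length_bands)]
            band_idx += 1
            len1 = int(rng.integers(lo, hi))
            jitter = int(rng.integers(0, slot - need + 1))
            start = margin + k * slot + jitter
            if rng.random() < cfg.het_frac:
                len2 = _distinct_length(len1, lo, hi, rng)
                truth.append(make_het_locus(cfg, chrom, start, len1, len2))
            else:
                truth.append(TruthRecord(chrom, start, len1, len1, "hom"))
    return truth


def _distinct_length(len1: int, lo: int, hi: int, rng: np.random.Generator) -> int:
    len2 = int(rng.integers(lo, hi))
    return len2 if len2 != len1 else len2 + 1 if len2 + 1 < hi else len2 - 1


def _split_counts(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


# ---------------------------------------------------------------------------
# Read construction


def _hap_deletions(truth: list[TruthRecord], chrom: str, hap: int) -> list[tuple[int, int]]:
    """(ref_start, length) of the deletions carried by one haplotype."""
    out = []
    for t in truth:
        if t.chrom != chrom:
            continue
        length = t.svlen_hap1 if hap == 1 else t.svlen_hap2
        if length > 0:
            out.append((t.start, length))
    return sorted(out)


def _build_read(
    hap_seq: str,
    dels: list[tuple[int, int]],  # (hap breakpoint, length), hap coords
    a: int,
    b: int,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[int, list[tuple[str, int]]]]:
    """Alignment segments for a read covering haplotype interval [a, b).

    Returns a list of (reference_offset_shift, cigar ops) segments: one
    segment for a contiguous alignment, two for a read crossing a deletion
    at or above ``split_rep_threshold``. The reference shift of a position
    is the total deleted length to its left on this haplotype.
    """
    inside = [(hs, ln) for hs, ln in dels if a < hs < b]
    segments: list[tuple[int, list[tuple[str, int]]]] = []
    ops: list[tuple[str, int]] = []
    shift = sum(ln for hs, ln in dels if hs <= a)
    seg_shift = shift
    cur = a
    trailing_adjust = 0
    for hs, ln in inside:
        ops.append(("M", hs - cur))
        cur = hs
        if ln >= cfg.split_rep_threshold:
            segments.append((seg_shift, ops))
            ops = []
            seg_shift = shift = shift + ln
        elif (
            cfg.frag_prob > 0
            and ln > cfg.frag_gap + 2
            and (b - hs) > cfg.frag_gap + 1
            and rng.random() < cfg.frag_prob
        ):
            l1 = ln // 2
            l2 = ln - l1 - cfg.frag_gap
            ops.extend([("D", l1), ("M", cfg.frag_gap), ("D", l2)])
            trailing_adjust += cfg.frag_gap
            shift += ln
        else:
            ops.append(("D", ln))
            shift += ln
    ops.append(("M", b - cur - trailing_adjust))
    segments.append((seg_shift, ops))
    return [(s, [op for op in o if op[1] > 0]) for s, o in segments]


def _segment_bounds(segments: list[tuple[int, list[tuple[str, int]]]]) -> list[tuple[int, int]]:
    """Query (start, end) of each segment within the read."""
    bounds = []
    q = 0
    for _, ops in segments:
        consumed = sum(l for op, l in ops if op in "MI=X")
        bounds.append((q, q + consumed))
        q += consumed
    return bounds


def simulate(
    cfg: SimConfig,
    outdir: str,
    truth: list[TruthRecord] | None = None,
) -> dict[str, str]:
    """Generate reference, truth set, and alignments; return output paths.

    Outputs (all under ``outdir``): ``ref.fa`` (+ ``.fai``), ``reads.sam``,
    ``reads.bam`` (+ ``.bai``), ``truth.tsv``, and ``truth.vcf``. Every
    byte is reproducible from ``cfg.seed``; passing an explicit ``truth``
    list overrides random placement (used for scripted scenarios such as a
    specific heterozygous locus).
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    if truth is None:
        truth = place_deletions(cfg, rng)
    truth = sorted(truth, key=lambda t: (t.chrom, t.start))
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    lengths = {c: cfg.chrom_length for c in chroms}

    ref_path = os.path.join(outdir, "ref.fa")
    ref_seqs: dict[str, str] = {}
    with open(ref_path, "w") as fh:
        for chrom in chroms:
            seq = _BASES[rng.integers(0, 4, cfg.chrom_length)].tobytes().decode()
            ref_seqs[chrom] = seq
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    Faidx(ref_path, rebuild=True)

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": lengths[c]} for c in chroms],
        }
    )
    records: list[pysam.AlignedSegment] = []
    for chrom in chroms:
        for hap in (1, 2):
            records.extend(
                _haplotype_reads(cfg, chrom, hap, ref_seqs[chrom], truth, header, rng)
            )
    records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name, r.flag))

    sam_path = os.path.join(outdir, "reads.sam")
    bam_path = os.path.join(outdir, "reads.bam")
    with pysam.AlignmentFile(sam_path, "wh", header=header) as out:
        for rec in records:
            out.write(rec)
    with pysam.AlignmentFile(bam_path, "wb", header=header) as out:
        for rec in records:
            out.write(rec)
    pysam.index(bam_path)

    tsv_path = os.path.join(outdir, "truth.tsv")
    with open(tsv_path, "w") as fh:
        fh.write("chrom\tstart\tsvlen_hap1\tsvlen_hap2\tzygosity\n")
        for t in truth:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.svlen_hap1}\t{t.svlen_hap2}\t{t.zygosity}\n"
            )

    vcf_path = os.path.join(outdir, "truth.vcf")
    truth_calls = []
    for i, t in enumerate(truth):
        for j, allele in enumerate(t.alleles()):
            truth_calls.append(
                DeletionCall(
                    chrom=t.chrom, start=t.start, svlen=allele,
                    end=t.start + allele, support=1, id=f"TRUTH.{i + 1}.{j + 1}",
                )
            )
    truth_calls.sort(key=lambda c: (c.chrom, c.start, c.svlen))
    write_vcf(truth_calls, vcf_path, chrom_lengths=lengths, reference=ref_path)

    return {
        "reference": ref_path, "sam": sam_path, "bam": bam_path,
        "truth_tsv": tsv_path, "truth_vcf": vcf_path,
    }


def _haplotype_reads(
    cfg: SimConfig,
    chrom: str,
    hap: int,
    ref_seq: str,
    truth: list[TruthRecord],
    header: pysam.AlignmentHeader,
    rng: np.random.Generator,
) -> list[pysam.AlignedSegment]:
    dels = _hap_deletions(truth, chrom, hap)
    pieces: list[str] = []
    prev = 0
    for s, ln in dels:
        pieces.append(ref_seq[prev:s])
        prev = s + ln
    pieces.append(ref_seq[prev:])
    hap_seq = "".join(pieces)
    # haplotype-coordinate breakpoints of the deletions
    hap_dels: list[tuple[int, int]] = []
    removed = 0
    for s, ln in dels:
        hap_dels.append((s - removed, ln))
        removed += ln
    per_hap_cov = cfg.coverage / 2.0
    step = max(1, int(round(cfg.read_length / per_hap_cov)))
    phase = 0 if hap == 1 else step // 2
    records: list[pysam.AlignedSegment] = []
    idx = 0
    for a in range(phase, max(1, len(hap_seq) - cfg.read_length + 1), step):
        b = a + cfg.read_length
        name = f"{chrom}_h{hap}_{idx:06d}"
        idx += 1
        segments = _build_read(hap_seq, hap_dels, a, b, cfg, rng)
        reverse = idx % 2 == 0
        recs = _emit_records(
            name, chrom, hap_seq[a:b], a, segments, header, reverse=reverse
        )
        records.extend(recs)
        if cfg.noise > 0 and rng.random() < cfg.noise:
            for rec in recs:
                dup = pysam.AlignedSegment(header)
                dup.set_tags(rec.get_tags())
                dup.query_name = rec.query_name + "_lowmq"
                dup.flag = rec.flag
                dup.reference_id = rec.reference_id
                dup.reference_start = rec.reference_start
                dup.mapping_quality = 10
                dup.cigarstring = rec.cigarstring
                dup.query_sequence = rec.query_sequence
                records.append(dup)
    return records


def _emit_records(
    name: str,
    chrom: str,
    seq: str,
    hap_a: int,
    segments: list[tuple[int, list[tuple[str, int]]]],
    header: pysam.AlignmentHeader,
    reverse: bool = False,
) -> list[pysam.AlignedSegment]:
    """SAM records for one read; two records + SA tags for a split read.

    For a reverse-strand read the stored (alignment-orientation) sequence
    and CIGAR are identical to the forward case; only the flag and the SA
    strand differ, which is exactly what an aligner reports for a read
    sequenced from the other strand of this haplotype.
    """
    bounds = _segment_bounds(segments)
    read_len = len(seq)
    recs: list[pysam.AlignedSegment] = []
    meta = []  # (ref_start, cigar string, for SA tags)
    strand = "-" if reverse else "+"
    for (shift, ops), (qs, qe) in zip(segments, bounds):
        # segment start sits at haplotype position hap_a + qs; adding the
        # deleted length to its left gives the reference position
        ref_start = hap_a + qs + shift
        cig_ops = []
        if qs > 0:
            cig_ops.append(("S", qs))
        cig_ops.extend(ops)
        if qe < read_len:
            cig_ops.append(("S", read_len - qe))
        cigar = "".join(f"{l}{op}" for op, l in cig_ops)
        meta.append((ref_start, cigar))
    for i, ((shift, ops), (qs, qe)) in enumerate(zip(segments, bounds)):
        rec = pysam.AlignedSegment(header)
        rec.query_name = name
        rec.reference_id = header.get_tid(chrom)
        rec.reference_start = meta[i][0]
        rec.mapping_quality = 60
        rec.cigarstring = meta[i][1]
        rec.query_sequence = seq
        flag = 0
        if reverse:
            flag |= 0x10
        if i > 0:
            flag |= 0x800
        rec.flag = flag
        if len(segments) > 1:
            sa = "".join(
                f"{chrom},{meta[j][0] + 1},{strand},{meta[j][1]},60,0;"
                for j in range(len(segments))
                if j != i
            )
            rec.set_tag("SA", sa)
        recs.append(rec)
    return recs
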