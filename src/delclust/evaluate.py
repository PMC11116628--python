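"""Benchmark a deletion call set against a truth set.

Matching follows the convention of SV benchmarking tools: a call matches a
truth allele when it lies on the same chromosome, its start is within
``refdist`` of the truth start, and the smaller length is at least
``pctsize`` of the larger. Matching is greedy one-to-one — each truth
allele takes the closest-start unmatched qualifying call. A heterozygous
locus with two different allele lengths contributes two truth alleles.

Only breakpoint distance and size similarity are compared; reciprocal
overlap and genotype concordance are deliberately not emulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pysam

from .simdata import DEFAULT_BANDS, TruthRecord


@dataclass(frozen=True)
class MatchConfig:
    refdist: int = 500
    pctsize: float = 0.7

    def __post_init__(self) -> None:
        if self.refdist < 0:
            raise ValueError("refdist must be non-negative")
        if not 0.0 < self.pctsize <= 1.0:
            raise ValueError("pctsize must lie in (0, 1]")


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    per_band: dict[str, "EvalReport"] | None = None

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else None

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return 0.0 if p is not None and r is not None else None
        return 2 * p * r / (p + r)

    def to_dict(self) -> dict:
        out = {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
        }
        if self.per_band is not None:
            out["bands"] = {k: v.to_dict() for k, v in self.per_band.items()}
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


# (chrom, start, length) triples are the common currency here.
Variant = tuple[str, int, int]


def load_vcf_deletions(path: str) -> list[Variant]:
    """Deletion records from a VCF; start is the 0-based first deleted base."""
    out: list[Variant] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            if svlen is None:
                continue
            out.append((rec.chrom, rec.start + 1, abs(int(svlen))))
    return sorted(out)


def load_truth_tsv(path: str) -> list[Variant]:
    """Truth alleles from the simulator's TSV (two per het_difflen locus)."""
    out: list[Variant] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            t = TruthRecord(
                chrom=row["chrom"], start=int(row["start"]),
                svlen_hap1=int(row["svlen_hap1"]), svlen_hap2=int(row["svlen_hap2"]),
                zygosity=row["zygosity"],
            )
            for allele in t.alleles():
                out.append((t.chrom, t.start, allele))
    return sorted(out)


def _qualifies(call: Variant, truth: Variant, cfg: MatchConfig) -> bool:
    if call[0] != truth[0]:
        return False
    if abs(call[1] - truth[1]) > cfg.refdist:
        return False
    lo, hi = sorted((call[2], truth[2]))
    return lo / hi >= cfg.pctsize


def match_calls(
    calls: list[Variant], truth: list[Variant], cfg: MatchConfig | None = None,
    bands: tuple[tuple[int, int], ...] | None = None,
) -> EvalReport:
    """Greedy one-to-one matching; returns overall and per-band tallies."""
    cfg = cfg or MatchConfig()
    calls = sorted(calls)
    truth = sorted(truth)
    matched_calls: set[int] = set()
    matched_truth: set[int] = set()
    for ti, t in enumerate(truth):
        best = None
        best_key = None
        for ci, c in enumerate(calls):
            if ci in matched_calls or not _qualifies(c, t, cfg):
                continue
            key = (abs(c[1] - t[1]), abs(c[2] - t[2]), ci)
            if best_key is None or key < best_key:
                best_key, best = key, ci
        if best is not None:
            matched_calls.add(best)
            matched_truth.add(ti)
    tp = len(matched_truth)
    report = EvalReport(tp=tp, fp=len(calls) - len(matched_calls), fn=len(truth) - tp)
    report.per_band = _stratify(calls, truth, matched_calls, matched_truth,
                                bands or DEFAULT_BANDS)
    return report


def _band_of(length: int, bands: tuple[tuple[int, int], ...]) -> str:
    for i, (lo, hi) in enumerate(bands):
        last = i == len(bands) - 1
        if lo <= length < hi or (last and length >= lo):
            return _band_label(bands, i)
    return _band_label(bands, len(bands) - 1)


def _band_label(bands: tuple[tuple[int, int], ...], i: int) -> str:
    lo, hi = bands[i]
    return f"[{lo},+)" if i == len(bands) - 1 else f"[{lo},{hi})"


def _stratify(calls, truth, matched_calls, matched_truth, bands):
    per = {
        _band_label(bands, i): EvalReport(0, 0, 0) for i in range(len(bands))
    }
    for ti, t in enumerate(truth):
        r = per[_band_of(t[2], bands)]
        if ti in matched_truth:
            r.tp += 1
        else:
            r.fn += 1
    for ci, c in enumerate(calls):
        if ci not in matched_calls:
            per[_band_of(c[2], bands)].fp += 1
    return per


def stratify_by_length(
    calls: list[Variant], truth: list[Variant],
    bands: tuple[tuple[int, int], ...] = DEFAULT_BANDS,
    cfg: MatchConfig | None = None,
) -> dict[str, EvalReport]:
    """Per-band precision/recall, band edges half-open ``[lo, hi)``."""
    return match_calls(calls, truth, cfg, bands).per_band
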