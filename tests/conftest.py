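"""Shared fixtures: hand-built SAM files and reusable simulated datasets."""

from __future__ import annotations

import pytest
import pysam

from delclust import (
    CallingConfig,
    ClusteringConfig,
    DeletionSignature,
    ExtractionConfig,
    SimConfig,
    call_pipeline,
    simulate,
)


def sig(start, svlen, end=None, chrom="chr1", read="r1", source="cigar"):
    """Shorthand DeletionSignature constructor for tests."""
    return DeletionSignature(
        chrom=chrom, start=start, svlen=svlen,
        end=start + svlen if end is None else end,
        read_name=read, source=source,
    )


def write_sam(path, records, lengths=None):
    """Write a SAM file from (name, flag, chrom, pos0, mapq, cigar[, tags]) rows."""
    lengths = lengths or {"chr1": 1_000_000}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": c, "LN": l} for c, l in lengths.items()],
        }
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for row in records:
            name, flag, chrom, pos, mapq, cigar = row[:6]
            rec = pysam.AlignedSegment(header)
            rec.query_name = name
            rec.flag = flag
            if chrom is not None:
                rec.reference_id = header.get_tid(chrom)
                rec.reference_start = pos
                rec.cigarstring = cigar
            rec.mapping_quality = mapq
            if len(row) > 6:
                for tag, value in row[6].items():
                    rec.set_tag(tag, value)
            out.write(rec)
    return str(path)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (used by unit and acceptance tests)


def sliding_window_oracle(starts, window):
    """Cluster start positions by window-index runs, not by re-sweeping.

    A cluster anchored at its first site s0 covers the consecutive windows
    [s0 + k*window, s0 + (k+1)*window) for k = 0..K-1, where K is the first
    window index containing no site; all sites falling in those windows form
    the cluster.
    """
    clusters = []
    rest = list(starts)
    while rest:
        s0 = rest[0]
        idx = [(s - s0) // window for s in rest]
        k = 0
        while k in idx:
            k += 1
        members = [s for s, i in zip(rest, idx) if i < k]
        clusters.append(members)
        rest = rest[len(members):]
    return clusters


def overlap_components_oracle(spans):
    """Connected components of the interval graph (touching intervals connect)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(spans)))
    for i, (a1, b1) in enumerate(spans):
        for j, (a2, b2) in enumerate(spans[i + 1:], start=i + 1):
            if a1 <= b2 and a2 <= b1:
                g.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(g)}


def greedy_agglomeration_oracle(lengths_with_starts, rate_threshold):
    """Naive re-derivation of the layer-2 agglomeration on (svlen, start) pairs.

    Returns the member index sets of the resulting one or two clusters,
    using the same deterministic tie-breaks as the implementation but
    recomputed from scratch each round with plain loops.
    """
    groups = [[i] for i in range(len(lengths_with_starts))]
    svlen = [p[0] for p in lengths_with_starts]
    start = [p[1] for p in lengths_with_starts]

    def mean(g):
        return sum(svlen[i] for i in g) / len(g)

    while len(groups) > 2:
        best, best_key = None, None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                mi, mj = mean(groups[i]), mean(groups[j])
                key = (
                    abs(mi - mj),
                    len(groups[i]) + len(groups[j]),
                    min(mi, mj),
                    min(min(start[k] for k in groups[i]),
                        min(start[k] for k in groups[j])),
                )
                if best_key is None or key < best_key:
                    best_key, best = key, (i, j)
        i, j = best
        groups[i] = groups[i] + groups[j]
        del groups[j]
    if len(groups) == 2:
        m1, m2 = mean(groups[0]), mean(groups[1])
        if abs(m1 - m2) / max(m1, m2) < rate_threshold:
            groups = [groups[0] + groups[1]]
    return {frozenset(g) for g in groups}


# ---------------------------------------------------------------------------
# Simulated datasets (session-scoped: reused across tests)


ZERO_NOISE_CFG = SimConfig(
    seed=42, n_chroms=1, chrom_length=2_000_000, n_deletions=20, coverage=20.0
)


@pytest.fixture(scope="session")
def zero_noise_sim(tmp_path_factory):
    """Seed-42 fixture: 2 Mb, 20 homozygous deletions over all length bands, 20x."""
    outdir = tmp_path_factory.mktemp("sim42")
    paths = simulate(ZERO_NOISE_CFG, str(outdir))
    return paths


@pytest.fixture(scope="session")
def zero_noise_calls(zero_noise_sim):
    return call_pipeline(
        zero_noise_sim["bam"], calling=CallingConfig(min_support=3)
    )
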