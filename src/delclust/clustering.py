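"""Two-layer clustering of deletion signatures.

Layer 1 groups signatures that describe the *same locus* into "large
clusters", with a size-stratified strategy: deletions of 2 kb and above are
clustered with a 1.5 kb sliding window over their start positions, while
smaller ones are clustered by the peaks of a per-base evidence-depth
profile (each signature's span increments the profile; a maximal run of
positive depth is one locus). The two strategies are independent and each
chromosome is processed independently, so the work parallelises trivially.

Layer 2 splits each large cluster by deletion *length*, because the two
homologous chromosomes may carry different-length deletions at one locus:
greedy agglomerative clustering on mean length runs until two clusters
remain; they are merged back into one only when their mean lengths differ
by less than 20% (the length-difference rate).
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

from .signatures import DeletionSignature


@dataclass(frozen=True)
class ClusteringConfig:
    """Layer-1/2 clustering parameters.

    Parameters
    ----------
    size_split
        Deletions with ``svlen >= size_split`` use the sliding-window
        method, smaller ones the coverage-peak method (default 2000 bp).
    window
        Sliding-window width (default 1500 bp).
    rate_threshold
        Two layer-2 clusters merge when their length-difference rate is
        strictly below this (default 0.20).
    chrom_lengths
        Contig lengths, used to clip signature spans for the depth profile.
    window_extension
        When the window starting at the previous window's end is nonempty,
        extend the *same* cluster (default). ``False`` flips to the
        alternative reading where every new window opens a new cluster;
        kept as an ablation hook.
    layer2_enabled
        Ablation hook: when ``False``, each large cluster passes through
        layer 2 unsplit (used to demonstrate why layer 2 exists).
    """

    size_split: int = 2000
    window: int = 1500
    rate_threshold: float = 0.20
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    window_extension: bool = True
    layer2_enabled: bool = True

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not 0.0 < self.rate_threshold < 1.0:
            raise ValueError("rate_threshold must lie in (0, 1)")
        if self.size_split <= 0:
            raise ValueError("size_split must be positive")


@dataclass(frozen=True)
class SignatureCluster:
    """A layer-1 cluster: signatures at one locus, one size class."""

    chrom: str
    members: tuple[DeletionSignature, ...]
    size_class: str  # 'small' | 'large'

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")
        if any(m.chrom != self.chrom for m in self.members):
            raise ValueError("all members must share the cluster chromosome")


@dataclass(frozen=True)
class CandidateCluster:
    """A layer-2 cluster; the unit of support filtering."""

    chrom: str
    members: tuple[DeletionSignature, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("candidate cluster must be nonempty")

    @property
    def mean_start(self) -> float:
        return sum(m.start for m in self.members) / len(self.members)

    @property
    def mean_len(self) -> float:
        return sum(m.svlen for m in self.members) / len(self.members)

    @property
    def support(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Layer 1


def partition_by_size(
    sigs: list[DeletionSignature], cfg: ClusteringConfig
) -> tuple[list[DeletionSignature], list[DeletionSignature]]:
    """Split signatures into (small, large) by ``svlen``.

    Equality at the threshold goes to *large* so borderline events get the
    positionally tighter window method.
    """
    small = [s for s in sigs if s.svlen < cfg.size_split]
    large = [s for s in sigs if s.svlen >= cfg.size_split]
    return small, large


def cluster_sliding_window(
    sites: list[DeletionSignature], cfg: ClusteringConfig
) -> list[SignatureCluster]:
    """Sliding-window clustering of large deletion sites on one chromosome.

    Sites must be sorted ascending by start. A window of width ``window``
    opens at the first unclustered site's start; every site starting inside
    the window joins the current cluster. The next window begins at the
    previous window's end: if it holds any site, those sites join the same
    cluster and the sweep continues; an empty window closes the cluster and
    the next cluster's window opens at the next site's start.
    """
    if any(sites[i].start > sites[i + 1].start for i in range(len(sites) - 1)):
        raise ValueError("cluster_sliding_window requires start-sorted input")
    clusters: list[SignatureCluster] = []
    n = len(sites)
    i = 0
    while i < n:
        members: list[DeletionSignature] = []
        window_start = sites[i].start
        while True:
            window_end = window_start + cfg.window
            captured = False
            while i < n and sites[i].start < window_end:
                members.append(sites[i])
                captured = True
                i += 1
            # The first window always captures its seed site; afterwards an
            # empty follow-on window (or exhausted input) closes the cluster.
            if not captured or i >= n or not cfg.window_extension:
                break
            window_start = window_end
        clusters.append(
            SignatureCluster(
                chrom=members[0].chrom, members=tuple(members), size_class="large"
            )
        )
    return clusters


def cluster_coverage(
    sites: list[DeletionSignature], cfg: ClusteringConfig
) -> list[SignatureCluster]:
    """Coverage-peak clustering of small deletion sites on one chromosome.

    Conceptually each site's span ``[start, end)`` increments a per-base
    evidence-depth profile; a maximal run of positions with depth >= 1 is a
    peak, and all sites inside one peak form one cluster. Implemented as a
    sweep over the sorted span breakpoints, which yields the maximal
    positive runs without materialising the profile.
    """
    if not sites:
        return []
    chrom = sites[0].chrom
    limit = cfg.chrom_lengths.get(chrom)
    spans: list[tuple[int, int, DeletionSignature]] = []
    for s in sites:
        end = s.end
        if limit is not None and end > limit:
            logging.getLogger("delclust").warning(
                "signature %s:%d-%d exceeds chromosome length %d; clipped",
                s.chrom, s.start, s.end, limit,
            )
            end = limit
        spans.append((s.start, max(end, s.start + 1), s))
    spans.sort(key=lambda t: (t[0], t[1]))
    clusters: list[SignatureCluster] = []
    run_end = None
    members: list[DeletionSignature] = []
    for start, end, sig in spans:
        if run_end is not None and start > run_end:
            clusters.append(
                SignatureCluster(chrom=chrom, members=tuple(members), size_class="small")
            )
            members = []
            run_end = None
        members.append(sig)
        run_end = end if run_end is None else max(run_end, end)
    if members:
        clusters.append(
            SignatureCluster(chrom=chrom, members=tuple(members), size_class="small")
        )
    return clusters


def layer1(
    sigs_by_chrom: dict[str, list[DeletionSignature]],
    cfg: ClusteringConfig,
    threads: int = 1,
) -> list[SignatureCluster]:
    """First-layer clustering over all chromosomes.

    Small and large sites are clustered independently per chromosome; the
    two methods never interact. Chromosomes are independent work items and
    may be processed by a thread pool; the result is sorted so it is
    byte-identical to serial execution.
    """

    def one_chrom(chrom: str) -> list[SignatureCluster]:
        sigs = sorted(sigs_by_chrom[chrom], key=lambda s: (s.start, s.svlen, s.read_name))
        small, large = partition_by_size(sigs, cfg)
        return cluster_coverage(small, cfg) + cluster_sliding_window(large, cfg)

    chroms = sorted(sigs_by_chrom)
    if threads > 1 and len(chroms) > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(one_chrom, chroms))
    else:
        results = [one_chrom(c) for c in chroms]
    out: list[SignatureCluster] = []
    for clusters in results:
        out.extend(clusters)
    out.sort(key=lambda c: (c.chrom, min(m.start for m in c.members), c.size_class))
    return out


# ---------------------------------------------------------------------------
# Layer 2


def length_difference_rate(len1: float, len2: float) -> float:
    """Relative length difference ``|len1 - len2| / max(len1, len2)``."""
    if len1 <= 0 or len2 <= 0:
        raise ValueError("lengths must be positive")
    return abs(len1 - len2) / max(len1, len2)


def hierarchical_cluster(
    cluster: SignatureCluster, cfg: ClusteringConfig
) -> list[CandidateCluster]:
    """Split one large cluster into one or two candidate clusters by length.

    Each member starts as a singleton; a cluster's length is the arithmetic
    mean of its members' ``svlen``. The pair of clusters with the smallest
    absolute mean-length difference merges, repeatedly, until exactly two
    clusters remain. The two survivors merge into one candidate cluster iff
    their length-difference rate is strictly below ``rate_threshold``;
    otherwise both are returned (two haplotypes, two deletion alleles).

    Ties in the minimum difference break by smaller combined member count,
    then smaller of the two means, then smaller earliest member start, so
    the result is deterministic under input permutation.
    """
    if not cfg.layer2_enabled:
        return [CandidateCluster(chrom=cluster.chrom, members=cluster.members)]
    groups: list[list[DeletionSignature]] = [
        [m] for m in sorted(cluster.members, key=lambda s: (s.start, s.svlen, s.read_name))
    ]
    while len(groups) > 2:
        best = None
        best_key = None
        for i in range(len(groups)):
            mi = _mean_len(groups[i])
            for j in range(i + 1, len(groups)):
                mj = _mean_len(groups[j])
                key = (
                    abs(mi - mj),
                    len(groups[i]) + len(groups[j]),
                    min(mi, mj),
                    min(min(s.start for s in groups[i]), min(s.start for s in groups[j])),
                )
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j)
        i, j = best  # type: ignore[misc]
        groups[i] = groups[i] + groups[j]
        del groups[j]
    if len(groups) == 1:
        return [CandidateCluster(chrom=cluster.chrom, members=tuple(groups[0]))]
    m1, m2 = _mean_len(groups[0]), _mean_len(groups[1])
    if length_difference_rate(m1, m2) < cfg.rate_threshold:
        merged = tuple(
            sorted(groups[0] + groups[1], key=lambda s: (s.start, s.svlen, s.read_name))
        )
        return [CandidateCluster(chrom=cluster.chrom, members=merged)]
    both = sorted(groups, key=lambda g: (_mean_len(g), min(s.start for s in g)))
    return [CandidateCluster(chrom=cluster.chrom, members=tuple(g)) for g in both]


def _mean_len(group: list[DeletionSignature]) -> float:
    return sum(s.svlen for s in group) / len(group)


def layer2(
    clusters: list[SignatureCluster], cfg: ClusteringConfig
) -> list[list[CandidateCluster]]:
    """Apply layer-2 clustering to every large cluster.

    Returns, per input cluster, its list of one or two candidate clusters;
    the grouping is kept because the support filter treats the one- and
    two-candidate cases differently.
    """
    return [hierarchical_cluster(c, cfg) for c in clusters]
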