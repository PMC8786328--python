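"""Density-based discovery of piRNA clusters on genomic coordinates.

The neighbourhood radius (eps) is estimated per chromosome from the
distribution of k-th-nearest-neighbour distances between read 5' ends
(the modal distance), then a one-dimensional DBSCAN groups reads into
clusters which are scored and classified by strandedness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_model import AlignedRead, GenomicInterval

__all__ = [
    "ClusterParams",
    "KDistProfile",
    "PiRNACluster",
    "ClusterResult",
    "EpsEstimationError",
    "kdist_profile",
    "estimate_eps",
    "dbscan_1d",
    "score_cluster",
    "classify_strandedness",
    "detect_clusters",
]

NOISE = -1

STRANDEDNESS = ("uni_plus", "uni_minus", "dual")


class EpsEstimationError(ValueError):
    """Raised when eps cannot be estimated; supply eps manually."""


@dataclass(frozen=True)
class ClusterParams:
    """DBSCAN parameters: neighbour order k, radius eps (bp), MinReads."""

    k: int = 4
    eps: int | None = None
    min_reads: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.eps is not None and self.eps < 1:
            raise ValueError("eps must be >= 1")
        if self.min_reads is not None and self.min_reads < 2:
            raise ValueError("min_reads must be >= 2")

    @property
    def effective_min_reads(self) -> int:
        # default MinReads = k + 1: the point itself plus its k neighbours
        return self.min_reads if self.min_reads is not None else self.k + 1


@dataclass
class KDistProfile:
    """Distances from each read 5' position to its k-th nearest neighbour."""

    chrom: str
    k: int
    distances: np.ndarray
    n_omitted: int = 0

    def __len__(self) -> int:
        return len(self.distances)

    def histogram(
        self, bin_width: float | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Histogram of the distances; Freedman-Diaconis width by default."""
        d = np.asarray(self.distances, dtype=float)
        if d.size == 0:
            raise EpsEstimationError(
                f"empty k-dist profile on {self.chrom}; supply eps manually"
            )
        if bin_width is None:
            bin_width = _fd_bin_width(d)
        edges = np.arange(0.0, d.max() + 2 * bin_width, bin_width)
        counts, edges = np.histogram(d, bins=edges)
        return edges, counts


def _fd_bin_width(d: np.ndarray) -> float:
    # Freedman-Diaconis width computed on the lower half of the
    # distribution: k-dist distributions mix a dense modal region (reads
    # inside clusters) with a very heavy background tail, and a tail-driven
    # IQR would smear the mode into one giant bin.
    lower = d[d <= np.median(d)]
    q75, q25 = np.percentile(lower, [75, 25])
    bw = 2.0 * (q75 - q25) / max(d.size, 1) ** (1.0 / 3.0)
    if bw <= 0:
        bw = 1.0
    return bw


@dataclass
class PiRNACluster:
    """A density-defined genomic interval of piRNA reads."""

    interval: GenomicInterval
    members: list[AlignedRead]
    score: float
    strandedness: str
    n_plus: int
    n_minus: int

    def __post_init__(self) -> None:
        if self.strandedness not in STRANDEDNESS:
            raise ValueError(f"bad strandedness {self.strandedness!r}")

    @property
    def n_reads(self) -> int:
        return len(self.members)


@dataclass
class ClusterResult:
    """Clusters plus the noise side-channel and per-chromosome parameters."""

    clusters: list[PiRNACluster]
    noise: list[AlignedRead]
    params_by_chrom: dict[str, ClusterParams] = field(default_factory=dict)


# ---------------------------------------------------------------------------


def kdist_profile(
    positions: Sequence[int] | np.ndarray, k: int, chrom: str = "."
) -> KDistProfile:
    """k-th nearest neighbour distance for every position (sorted input).

    Positions with fewer than ``k`` other reads on the chromosome are
    omitted and counted in ``n_omitted``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pos = np.asarray(positions, dtype=np.int64)
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted ascending")
    n = pos.size
    if n < k + 1:
        if n:
            warnings.warn(
                f"{chrom}: only {n} reads, fewer than k+1={k + 1}; "
                "k-dist profile is empty",
                stacklevel=2,
            )
        return KDistProfile(chrom, k, np.array([], dtype=np.int64), n_omitted=n)
    dists = np.empty(n, dtype=np.int64)
    for i in range(n):
        lo = max(0, i - k)
        hi = min(n, i + k + 1)
        cand = np.abs(np.concatenate([pos[lo:i], pos[i + 1 : hi]]) - pos[i])
        dists[i] = np.partition(cand, k - 1)[k - 1]
    return KDistProfile(chrom, k, dists, n_omitted=0)


def estimate_eps(
    profile: KDistProfile, bin_width: float | None = None
) -> int:
    """Pick eps as the upper edge of the modal k-dist histogram bin.

    Ties between equally tall bins are broken toward the smaller distance.
    """
    edges, counts = profile.histogram(bin_width)  # raises on empty profile
    modal = int(np.argmax(counts))  # argmax takes the first (smallest) bin
    eps = int(math.ceil(edges[modal + 1]))
    return max(eps, 1)


def dbscan_1d(
    positions: Sequence[int] | Sequence[tuple[int, str]] | np.ndarray,
    eps: int,
    min_reads: int,
) -> np.ndarray:
    """Classic DBSCAN on one genomic axis.

    A read is *core* if at least ``min_reads`` reads (itself included) lie
    within +/- eps of it; clusters are maximal density-connected sets of
    core points plus border points. Border points reachable from more than
    one cluster are attached to the cluster of their nearest core point
    (ties toward the smaller coordinate), which makes the labelling
    independent of input order. Returns one label per input read in input
    order; noise is labelled -1.
    """
    if eps < 1:
        raise ValueError("eps must be >= 1")
    if min_reads < 2:
        raise ValueError("min_reads must be >= 2")
    raw = list(positions)
    if raw and isinstance(raw[0], (tuple, list)):
        raw = [p for p, _ in raw]
    pos = np.asarray(raw, dtype=np.int64)
    n = pos.size
    labels = np.full(n, NOISE, dtype=np.int64)
    if n == 0:
        return labels
    order = np.argsort(pos, kind="stable")
    sp = pos[order]
    left = np.searchsorted(sp, sp - eps, side="left")
    right = np.searchsorted(sp, sp + eps, side="right")
    core = (right - left) >= min_reads

    sorted_labels = np.full(n, NOISE, dtype=np.int64)
    cid = -1
    prev_core = None
    for i in range(n):
        if not core[i]:
            continue
        if prev_core is None or sp[i] - prev_core > eps:
            cid += 1
        sorted_labels[i] = cid
        prev_core = sp[i]

    core_pos = sp[core]
    core_lab = sorted_labels[core]
    if core_pos.size:
        for i in np.nonzero(~core)[0]:
            j = np.searchsorted(core_pos, sp[i])
            best = None  # (distance, core position, label)
            if j > 0:
                best = (sp[i] - core_pos[j - 1], core_pos[j - 1], core_lab[j - 1])
            if j < core_pos.size:
                cand = (core_pos[j] - sp[i], core_pos[j], core_lab[j])
                if best is None or cand[0] < best[0]:
                    best = cand
            if best is not None and best[0] <= eps:
                sorted_labels[i] = best[2]

    labels[order] = sorted_labels
    return labels


def score_cluster(
    n_reads: int, min_reads: int, k: int | None = None, scale_by_k: bool = False
) -> float:
    """Cluster enrichment score: reads in the cluster over the minimum
    count needed to form one.

    With ``scale_by_k`` the denominator becomes ``min_reads * k``
    (alternative reading of the score definition). Scores below 1 are
    possible for clusters that lost shared border points to a neighbour.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    denom = min_reads * k if scale_by_k and k else min_reads
    return n_reads / denom


def classify_strandedness(
    members: Sequence[AlignedRead],
) -> tuple[str, int, int]:
    """Label a cluster uni_plus / uni_minus / dual from member strands.

    Returns ``(label, n_plus, n_minus)``.
    """
    if not members:
        raise ValueError("cannot classify an empty cluster")
    n_plus = sum(1 for m in members if m.strand == "+")
    n_minus = sum(1 for m in members if m.strand == "-")
    if n_plus + n_minus != len(members):
        raise ValueError("all members must carry an explicit strand (+/-)")
    if n_plus and n_minus:
        return "dual", n_plus, n_minus
    return ("uni_plus" if n_plus else "uni_minus"), n_plus, n_minus


def _group_by_chrom(reads: Iterable[AlignedRead]) -> dict[str, list[AlignedRead]]:
    grouped: dict[str, list[AlignedRead]] = {}
    for r in reads:
        grouped.setdefault(r.chrom, []).append(r)
    return grouped


def detect_clusters(
    reads: Sequence[AlignedRead] | Mapping[str, Sequence[AlignedRead]],
    params: ClusterParams | None = None,
    bin_width: float | None = None,
    scale_score_by_k: bool = False,
) -> ClusterResult:
    """Run the full pipeline per chromosome: (optional) eps estimation from
    the k-dist profile, DBSCAN, scoring and strandedness classification.

    Clusters are returned sorted by chromosome then start; reads not
    assigned to any cluster are reported as noise, never dropped.
    """
    if params is None:
        params = ClusterParams()
    grouped = (
        {c: list(v) for c, v in reads.items()}
        if isinstance(reads, Mapping)
        else _group_by_chrom(reads)
    )
    clusters: list[PiRNACluster] = []
    noise: list[AlignedRead] = []
    params_log: dict[str, ClusterParams] = {}
    for chrom in sorted(grouped):
        chrom_reads = sorted(grouped[chrom], key=lambda r: r.five_prime)
        positions = np.array([r.five_prime for r in chrom_reads], dtype=np.int64)
        if params.eps is None:
            profile = kdist_profile(positions, params.k, chrom=chrom)
            eps = estimate_eps(profile, bin_width)  # propagates empty-profile error
        else:
            eps = params.eps
        min_reads = params.effective_min_reads
        params_log[chrom] = ClusterParams(params.k, eps, min_reads)
        labels = dbscan_1d(positions, eps, min_reads)
        for cid in np.unique(labels):
            members = [r for r, lab in zip(chrom_reads, labels) if lab == cid]
            if cid == NOISE:
                noise.extend(members)
                continue
            strandedness, n_plus, n_minus = classify_strandedness(members)
            interval = GenomicInterval(
                chrom,
                min(m.interval.start for m in members),
                max(m.interval.end for m in members),
            )
            clusters.append(
                PiRNACluster(
                    interval=interval,
                    members=members,
                    score=score_cluster(
                        len(members), min_reads, params.k, scale_score_by_k
                    ),
                    strandedness=strandedness,
                    n_plus=n_plus,
                    n_minus=n_minus,
                )
            )
    clusters.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return ClusterResult(clusters, noise, params_log)
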