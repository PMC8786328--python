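"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (all-pairs
enumeration, per-base counting, exhaustive alignment search) so that they
stay independent of the library code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np

from pirnakit.targets import ScoringParams, _column_score


def brute_dbscan(positions, eps, min_reads):
    """Density-reachability closure by explicit graph construction.

    Core points: >= min_reads points (self included) within eps. Clusters:
    connected components of the core-core adjacency (distance <= eps) plus
    border points, each border attached to its nearest core (ties toward
    the smaller coordinate). Returns labels aligned with input order.
    """
    pos = np.asarray(positions, dtype=np.int64)
    n = pos.size
    within = np.abs(pos[:, None] - pos[None, :]) <= eps
    core = within.sum(axis=1) >= min_reads
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if core[i] and core[j] and within[i, j]:
                parent[find(i)] = find(j)
    labels = np.full(n, -1, dtype=int)
    roots: dict[int, int] = {}
    for i in range(n):
        if core[i]:
            r = find(i)
            labels[i] = roots.setdefault(r, len(roots))
    for i in range(n):
        if core[i]:
            continue
        best = None  # (distance, core position, label)
        for j in range(n):
            if core[j] and within[i, j]:
                cand = (abs(int(pos[i]) - int(pos[j])), int(pos[j]), labels[j])
                if best is None or cand[:2] < best[:2]:
                    best = cand
        if best is not None:
            labels[i] = best[2]
    return labels


def partition(positions, labels):
    """Canonical (noise multiset, cluster multisets) representation,
    insensitive to label numbering, keyed by position index."""
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(idx)
    noise = frozenset(groups.get(-1, []))
    clusters = frozenset(
        frozenset(v) for lab, v in groups.items() if lab != -1
    )
    return noise, clusters


def brute_kdist(positions, k):
    """All-pairs k-th smallest distance per point; omits points with
    fewer than k neighbours."""
    pos = list(positions)
    out = []
    omitted = 0
    for i, p in enumerate(pos):
        dists = sorted(abs(p - q) for j, q in enumerate(pos) if j != i)
        if len(dists) < k:
            omitted += 1
        else:
            out.append(dists[k - 1])
    return out, omitted


def brute_overlap_pairs(reads, max_overlap=None, exact=None):
    """All-pairs cross-strand 5' overlap enumeration.

    Returns a list of (plus_read, minus_read, overlap) for every
    intersecting opposite-strand pair with overlap >= 1, optionally
    filtered by an exact overlap or a maximum.
    """
    out = []
    for a in reads:
        for b in reads:
            if a.strand != "+" or b.strand != "-":
                continue
            if a.chrom != b.chrom:
                continue
            if not (
                a.interval.start < b.interval.end
                and b.interval.start < a.interval.end
            ):
                continue
            p = a.interval.start
            q = b.interval.end - 1
            if q < p:
                continue
            overlap = q - p + 1
            if exact is not None and overlap != exact:
                continue
            if max_overlap is not None and overlap > max_overlap:
                continue
            out.append((a, b, overlap))
    return out


def per_base_overlap(interval, features):
    """Count overlap bp by marking individual bases (union semantics)."""
    covered = set()
    for f in features:
        if f.chrom != interval.chrom:
            continue
        lo = max(interval.start, f.start)
        hi = min(interval.end, f.end)
        covered.update(range(lo, hi))
    return len(covered)


def _gap_cost(g: int, params: ScoringParams) -> float:
    return 0.0 if g == 0 else params.gap_open + params.gap_extend * (g - 1)


def brute_align_score(query, target, weights, params: ScoringParams) -> float:
    """Exhaustive local alignment: enumerate every monotone set of aligned
    columns; unaligned residues between consecutive columns cost affine
    gap penalties in each sequence. Only feasible for tiny instances.
    """
    nq, nt = len(query), len(target)
    best = 0.0
    for k in range(1, min(nq, nt) + 1):
        for qi in itertools.combinations(range(nq), k):
            for ti in itertools.combinations(range(nt), k):
                s = 0.0
                for idx in range(k):
                    cs, _ = _column_score(query[qi[idx]], target[ti[idx]], params)
                    s += cs * weights[qi[idx]]
                    if idx:
                        s += _gap_cost(qi[idx] - qi[idx - 1] - 1, params)
                        s += _gap_cost(ti[idx] - ti[idx - 1] - 1, params)
                best = max(best, s)
    return best
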