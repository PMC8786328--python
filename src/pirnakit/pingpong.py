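"""Ping-pong partner detection via the 10-nt 5'-to-5' overlap rule.

The overlap between a plus-strand read with 5' end at genomic position p
and a minus-strand read with 5' end at q is ``q - p + 1``, defined only
when the two read intervals intersect and q >= p. Sequence content is not
consulted; the signature is purely positional.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_model import AlignedRead

__all__ = [
    "PingPongPair",
    "OverlapSignature",
    "five_prime_overlap",
    "find_pingpong_pairs",
    "overlap_signature",
]


@dataclass(frozen=True)
class PingPongPair:
    plus_read: AlignedRead
    minus_read: AlignedRead
    overlap_len: int

    def __post_init__(self) -> None:
        if self.overlap_len < 1:
            raise ValueError("overlap_len must be >= 1")


@dataclass
class OverlapSignature:
    """Histogram of 5' overlap lengths over opposite-strand read pairs."""

    counts: dict[int, int]
    peak: int | None

    @property
    def total_pairs(self) -> int:
        return sum(self.counts.values())


def five_prime_overlap(plus_read: AlignedRead, minus_read: AlignedRead) -> int | None:
    """5'-to-5' overlap in nt, or None if the reads do not overlap."""
    if plus_read.strand != "+" or minus_read.strand != "-":
        raise ValueError("expected a plus-strand and a minus-strand read")
    if plus_read.chrom != minus_read.chrom:
        return None
    if not plus_read.interval.overlaps(minus_read.interval):
        return None
    p = plus_read.five_prime
    q = minus_read.five_prime
    if q < p:
        return None
    return q - p + 1


def _split_by_strand(
    reads: Sequence[AlignedRead],
) -> tuple[dict[str, list[AlignedRead]], dict[str, list[AlignedRead]]]:
    plus: dict[str, list[AlignedRead]] = defaultdict(list)
    minus: dict[str, list[AlignedRead]] = defaultdict(list)
    for r in reads:
        if r.strand == "+":
            plus[r.chrom].append(r)
        elif r.strand == "-":
            minus[r.chrom].append(r)
    return plus, minus


def find_pingpong_pairs(
    reads: Sequence[AlignedRead], target_overlap: int = 10
) -> list[PingPongPair]:
    """All cross-strand read pairs whose 5' overlap equals ``target_overlap``.

    A read may participate in several pairs. Output is sorted by
    chromosome, then plus-read 5' position, then minus-read start.
    """
    if target_overlap < 1:
        raise ValueError("target_overlap must be >= 1")
    plus_by_chrom, minus_by_chrom = _split_by_strand(reads)
    pairs: list[PingPongPair] = []
    for chrom in sorted(set(plus_by_chrom) & set(minus_by_chrom)):
        by_q: dict[int, list[AlignedRead]] = defaultdict(list)
        for m in minus_by_chrom[chrom]:
            by_q[m.five_prime].append(m)
        for p_read in sorted(plus_by_chrom[chrom], key=lambda r: (r.five_prime, r.read_id)):
            q = p_read.five_prime + target_overlap - 1
            for m_read in sorted(by_q.get(q, ()), key=lambda r: (r.interval.start, r.read_id)):
                if p_read.interval.overlaps(m_read.interval):
                    pairs.append(PingPongPair(p_read, m_read, target_overlap))
    return pairs


def overlap_signature(
    reads: Sequence[AlignedRead], max_overlap: int = 20
) -> OverlapSignature:
    """Histogram of 5' overlaps (1..max_overlap) over all intersecting
    cross-strand pairs; the peak is the modal overlap length (ties broken
    toward the shorter overlap), or None when no pair overlaps.
    """
    if max_overlap < 1:
        raise ValueError("max_overlap must be >= 1")
    plus_by_chrom, minus_by_chrom = _split_by_strand(reads)
    counts: dict[int, int] = defaultdict(int)
    for chrom in set(plus_by_chrom) & set(minus_by_chrom):
        minus_reads = sorted(minus_by_chrom[chrom], key=lambda r: r.five_prime)
        qs = np.array([m.five_prime for m in minus_reads], dtype=np.int64)
        for p_read in plus_by_chrom[chrom]:
            p = p_read.five_prime
            lo = np.searchsorted(qs, p, side="left")
            hi = np.searchsorted(qs, p + max_overlap - 1, side="right")
            for m_read in minus_reads[lo:hi]:
                if p_read.interval.overlaps(m_read.interval):
                    counts[m_read.five_prime - p + 1] += 1
    if not counts:
        return OverlapSignature({}, None)
    peak = min(counts, key=lambda L: (-counts[L], L))
    return OverlapSignature(dict(sorted(counts.items())), peak)
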