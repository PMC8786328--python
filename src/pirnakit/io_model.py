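"""Core genomic data types, BED/FASTA readers and writers, sequence collapse
and piRNA identifier assignment.

All coordinates are 0-based half-open (BED convention) throughout the
package; any 1-based source must be converted at the reader boundary.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "AlignedRead",
    "PiRNARecord",
    "AnnotationSet",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "collapse_redundant",
    "assign_ids",
    "screen_putative_pirnas",
    "normalize_sequence",
]

STRANDS = ("+", "-", ".")

ANNOTATION_CATEGORIES = (
    "gene",
    "exon",
    "CDS",
    "utr5",
    "utr3",
    "intron",
    "repeat",
    "pseudogene",
    "lncRNA",
)

_SEQ_RE = re.compile(r"^[ACGTUN]+$")
_ABBR_RE = re.compile(r"^[a-z]{3}$")


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed; carries the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class AlignedRead:
    """One mapped small-RNA read locus.

    ``copy_count`` is the number of identical sequences collapsed into this
    locus; ``score`` preserves BED column 5 for round-tripping.
    """

    interval: GenomicInterval
    read_id: str
    copy_count: int = 1
    score: int = 0

    def __post_init__(self) -> None:
        if self.copy_count < 1:
            raise ValueError("copy_count must be >= 1")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the read 5' end (strand-aware)."""
        if self.interval.strand == "+":
            return self.interval.start
        if self.interval.strand == "-":
            return self.interval.end - 1
        raise ValueError(
            f"read {self.read_id} is unstranded; 5' end undefined"
        )


@dataclass
class PiRNARecord:
    """A non-redundant piRNA sequence with its identifier and mapped loci."""

    pirna_id: str
    sequence: str
    loci: list[GenomicInterval] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        s = self.sequence.upper()
        return (s.count("G") + s.count("C")) / len(s)


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T; reject non-nucleotide characters."""
    s = seq.upper().replace("U", "T")
    if not s or not _SEQ_RE.match(s):
        raise ValueError(f"non-nucleotide characters in sequence {seq!r}")
    return s


class AnnotationSet:
    """A category of genomic features indexed per chromosome for overlap queries.

    Each feature is an interval plus an optional name (for repeats, the
    repeat family). ``sub_family`` may only be set on repeat sets.
    """

    def __init__(
        self,
        category: str,
        features: Iterable[tuple[GenomicInterval, str | None]] = (),
        sub_family: str | None = None,
    ) -> None:
        if category not in ANNOTATION_CATEGORIES:
            raise ValueError(f"unknown annotation category {category!r}")
        if sub_family is not None and category != "repeat":
            raise ValueError("sub_family may only be set for repeat sets")
        self.category = category
        self.sub_family = sub_family
        self._features: list[tuple[GenomicInterval, str | None]] = []
        self._index: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] | None = None
        for iv, name in features:
            self.add(iv, name)

    def add(self, interval: GenomicInterval, name: str | None = None) -> None:
        self._features.append((interval, name))
        self._index = None

    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self) -> Iterator[tuple[GenomicInterval, str | None]]:
        return iter(self._features)

    @property
    def chroms(self) -> set[str]:
        return {iv.chrom for iv, _ in self._features}

    def _build_index(self) -> dict[str, tuple[np.ndarray, np.ndarray, list[int]]]:
        if self._index is None:
            by_chrom: dict[str, list[int]] = defaultdict(list)
            for i, (iv, _) in enumerate(self._features):
                by_chrom[iv.chrom].append(i)
            index = {}
            for chrom, idxs in by_chrom.items():
                idxs.sort(key=lambda i: self._features[i][0].start)
                starts = np.array([self._features[i][0].start for i in idxs])
                ends = np.array([self._features[i][0].end for i in idxs])
                index[chrom] = (starts, ends, idxs)
            self._index = index
        return self._index

    def overlaps(
        self, interval: GenomicInterval
    ) -> list[tuple[GenomicInterval, str | None, int]]:
        """All features overlapping ``interval`` with overlap lengths in bp."""
        index = self._build_index()
        if interval.chrom not in index:
            return []
        starts, ends, idxs = index[interval.chrom]
        hit = np.nonzero((starts < interval.end) & (ends > interval.start))[0]
        out = []
        for h in hit:
            iv, name = self._features[idxs[h]]
            out.append((iv, name, iv.overlap_bp(interval)))
        return out

    def any_overlap(self, interval: GenomicInterval) -> bool:
        index = self._build_index()
        if interval.chrom not in index:
            return False
        starts, ends, _ = index[interval.chrom]
        return bool(np.any((starts < interval.end) & (ends > interval.start)))

    @classmethod
    def from_bed(cls, path: str | Path, category: str) -> "AnnotationSet":
        """Load a BED file as an annotation set; column 4 becomes the name."""
        reads = read_bed(path)
        return cls(
            category,
            ((r.interval, r.read_id or None) for r in reads),
        )


# ---------------------------------------------------------------------------
# Readers / writers


def read_bed(path: str | Path) -> list[AlignedRead]:
    """Parse a BED3+/BED6 file into :class:`AlignedRead` records.

    Missing strand becomes ``"."``; duplicate lines are preserved (no
    deduplication at the read stage).
    """
    records: list[AlignedRead] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 columns, got {len(cols)}"
                )
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = cols[3] if len(cols) > 3 else f"read{lineno}"
            try:
                score = int(float(cols[4])) if len(cols) > 4 else 0
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: bad score column") from exc
            strand = cols[5] if len(cols) > 5 else "."
            if strand not in STRANDS:
                raise BedParseError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                interval = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(AlignedRead(interval, name, score=score))
    return records


def write_bed(reads: Sequence[AlignedRead], path: str | Path) -> None:
    """Write reads as BED6 (name = read_id, score column preserved)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(
                f"{r.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.read_id}\t{r.score}\t{r.strand}\n"
            )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Redundancy collapse and ID assignment


def collapse_redundant(
    sequences: Sequence[tuple[str, str]],
) -> list[tuple[str, int, list[str]]]:
    """Collapse identical sequences (U/T-equivalent) into unique entries.

    Returns ``(sequence, copy_count, member_ids)`` tuples ordered by
    descending copy count, then lexicographic sequence. Total copy counts
    equal the number of input sequences.
    """
    groups: dict[str, list[str]] = {}
    for seq_id, seq in sequences:
        norm = normalize_sequence(seq)
        groups.setdefault(norm, []).append(seq_id)
    out = [(seq, len(ids), ids) for seq, ids in groups.items()]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def assign_ids(
    species_abbr: str,
    collapsed: Sequence[str] | Sequence[tuple[str, int, list[str]]],
) -> list[PiRNARecord]:
    """Assign ``{abbr}_piRNA_{i}`` identifiers (i = 1..N) in input order."""
    if not _ABBR_RE.match(species_abbr):
        raise ValueError(
            f"species abbreviation must be three lowercase letters, got "
            f"{species_abbr!r}"
        )
    records = []
    for i, entry in enumerate(collapsed, start=1):
        seq = entry if isinstance(entry, str) else entry[0]
        records.append(
            PiRNARecord(f"{species_abbr}_piRNA_{i}", normalize_sequence(seq))
        )
    return records


def screen_putative_pirnas(
    records: Sequence[PiRNARecord],
    min_len: int = 24,
    max_len: int = 33,
    exclude: AnnotationSet | None = None,
) -> list[PiRNARecord]:
    """Retain records within the length window whose loci avoid the
    exclusion set (e.g. other annotated ncRNA loci).

    The default 24-33 nt window suits most species; override per species
    (e.g. 21 nt for nematode 21U-RNAs).
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    kept = []
    for rec in records:
        if not (min_len <= rec.length <= max_len):
            continue
        if exclude is not None and any(
            exclude.any_overlap(locus) for locus in rec.loci
        ):
            continue
        kept.append(rec)
    return kept
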