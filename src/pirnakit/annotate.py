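"""Genomic-context classification of piRNA loci and clusters, and remapping
of cluster coordinates through synteny blocks."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .cluster import PiRNACluster
from .io_model import AnnotationSet, GenomicInterval

__all__ = [
    "LocusClassification",
    "SyntenyBlock",
    "PRIMARY_PRECEDENCE",
    "REPEAT_FAMILIES",
    "classify_locus",
    "cluster_feature_overlap",
    "remap_through_synteny",
    "introns_from_exons",
]

# most-specific feature wins; configurable via the `precedence` argument
PRIMARY_PRECEDENCE = ("CDS", "utr5", "utr3", "exon_other", "intron")

# canonical repeat families; anything else is reported as "other"
REPEAT_FAMILIES = (
    "LINE",
    "SINE",
    "LTR",
    "DNA",
    "Simple_repeat",
    "Low_complexity",
    "Satellite",
)

_CATEGORY_TO_SET = {
    "CDS": "CDS",
    "utr5": "utr5",
    "utr3": "utr3",
    "exon_other": "exon",
    "intron": "intron",
}


@dataclass
class LocusClassification:
    pirna_id: str
    primary_category: str
    repeat_overlaps: list[tuple[str, int]] = field(default_factory=list)
    pseudogene_overlap: bool = False
    lncRNA_overlap: bool = False


@dataclass(frozen=True)
class SyntenyBlock:
    """A source interval mapped to a target-species interval."""

    source: GenomicInterval
    target_species: str
    target: GenomicInterval
    orientation: str = "same"

    def __post_init__(self) -> None:
        if self.orientation not in ("same", "flipped"):
            raise ValueError(f"bad orientation {self.orientation!r}")


def _min_overlap_bp(locus: GenomicInterval, min_overlap: int, min_fraction: float | None) -> int:
    if min_fraction is not None:
        return max(min_overlap, int(round(min_fraction * len(locus))))
    return min_overlap


def classify_locus(
    locus: GenomicInterval,
    annotations: Mapping[str, AnnotationSet],
    pirna_id: str = ".",
    precedence: Sequence[str] = PRIMARY_PRECEDENCE,
    min_overlap: int = 1,
    min_fraction: float | None = None,
) -> LocusClassification:
    """Assign exactly one primary genomic category to a locus.

    ``annotations`` maps category names (as in :data:`PRIMARY_PRECEDENCE`
    plus ``repeat``/``pseudogene``/``lncRNA``) to annotation sets. The
    primary category is the first category in ``precedence`` with an
    overlap of at least ``min_overlap`` bp (or ``min_fraction`` of the
    locus length); otherwise ``intergenic``. Repeat, pseudogene and lncRNA
    overlaps are reported independently.
    """
    threshold = _min_overlap_bp(locus, min_overlap, min_fraction)
    known_chrom = any(
        locus.chrom in aset.chroms for aset in annotations.values()
    )
    if annotations and not known_chrom:
        warnings.warn(
            f"chromosome {locus.chrom} absent from all annotation sets; "
            "classifying as intergenic",
            stacklevel=2,
        )

    primary = "intergenic"
    for category in precedence:
        aset = annotations.get(_CATEGORY_TO_SET.get(category, category))
        if aset is None:
            continue
        if any(bp >= threshold for _, _, bp in aset.overlaps(locus)):
            primary = category
            break

    repeat_overlaps: list[tuple[str, int]] = []
    repeats = annotations.get("repeat")
    if repeats is not None:
        for _, family, bp in repeats.overlaps(locus):
            if bp >= threshold:
                fam = family if family in REPEAT_FAMILIES else "other"
                repeat_overlaps.append((fam, bp))

    def _hit(cat: str) -> bool:
        aset = annotations.get(cat)
        return aset is not None and any(
            bp >= threshold for _, _, bp in aset.overlaps(locus)
        )

    return LocusClassification(
        pirna_id=pirna_id,
        primary_category=primary,
        repeat_overlaps=repeat_overlaps,
        pseudogene_overlap=_hit("pseudogene"),
        lncRNA_overlap=_hit("lncRNA"),
    )


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total covered length of possibly-overlapping (start, end) pairs."""
    if not intervals:
        return 0
    intervals.sort()
    total = 0
    cur_start, cur_end = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_end:
            total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    return total + (cur_end - cur_start)


def cluster_feature_overlap(
    clusters: Sequence[PiRNACluster] | Sequence[GenomicInterval],
    features: AnnotationSet,
) -> pd.DataFrame:
    """Per-cluster overlap with a feature set.

    The overlap is the length of the union of all intersections, so
    overlapping features are not double-counted. Returns one row per
    cluster with columns chrom/start/end/overlapped/overlap_bp/feature_ids.
    """
    rows = []
    for c in clusters:
        interval = c.interval if isinstance(c, PiRNACluster) else c
        hits = features.overlaps(interval)
        pieces = [
            (max(iv.start, interval.start), min(iv.end, interval.end))
            for iv, _, _ in hits
        ]
        names = sorted({name for _, name, _ in hits if name is not None})
        bp = _union_length(pieces)
        rows.append(
            {
                "chrom": interval.chrom,
                "start": interval.start,
                "end": interval.end,
                "overlapped": bp > 0,
                "overlap_bp": bp,
                "feature_ids": ",".join(names),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "overlapped", "overlap_bp", "feature_ids"],
    )


def remap_through_synteny(
    interval: GenomicInterval, blocks: Sequence[SyntenyBlock]
) -> list[GenomicInterval]:
    """Project the portion of ``interval`` inside each synteny block into
    the block's target coordinates by linear interpolation, reflecting the
    coordinates when the block orientation is flipped.

    Returns one target interval per intersecting block (possibly empty).
    """
    out: list[GenomicInterval] = []
    for block in blocks:
        src, tgt = block.source, block.target
        if not interval.overlaps(src):
            continue
        cs = max(interval.start, src.start)
        ce = min(interval.end, src.end)
        f0 = (cs - src.start) / len(src)
        f1 = (ce - src.start) / len(src)
        tl = len(tgt)
        if block.orientation == "same":
            a = tgt.start + int(round(f0 * tl))
            b = tgt.start + int(round(f1 * tl))
        else:
            a = tgt.start + int(round((1.0 - f1) * tl))
            b = tgt.start + int(round((1.0 - f0) * tl))
        if b <= a:
            b = a + 1
        out.append(GenomicInterval(tgt.chrom, a, b, tgt.strand))
    return out


def introns_from_exons(
    gene: GenomicInterval, exons: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Helper: derive intron intervals as the gaps between sorted exons
    within a gene span."""
    sorted_exons = sorted(
        (e for e in exons if e.chrom == gene.chrom), key=lambda e: e.start
    )
    introns = []
    for left, right in zip(sorted_exons, sorted_exons[1:]):
        if right.start > left.end:
            introns.append(
                GenomicInterval(gene.chrom, left.end, right.start, gene.strand)
            )
    return introns
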