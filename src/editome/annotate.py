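"""Genic-region and repeat-element annotation by interval intersection.

Region labels follow a documented precedence across transcripts
(CDS > 3'UTR > 5'UTR > noncoding-exon > intron; no overlap = intergenic).
Repeat intersection uses the BED half-open convention: a 1-based site p
intersects [s, e) iff s < p <= e; among overlapping repeats the longest
containing interval wins, ties broken by sorted order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._stats import share_table
from .reference import (
    RepeatFeature,
    Transcript,
    build_repeat_index,
    build_transcript_index,
    features_at,
)

REGION_PRECEDENCE = ("CDS", "3'UTR", "5'UTR", "noncoding-exon", "intron")
INTERGENIC = "intergenic"


@dataclass(frozen=True)
class GenicAssignment:
    chrom: str
    pos: int
    region: str
    gene_ids: tuple[str, ...]
    transcript_id: str | None


@dataclass(frozen=True)
class RepeatAssignment:
    chrom: str
    pos: int
    in_repeat: bool
    class_family: str | None  # e.g. "SINE/tRNA"
    element: str | None  # e.g. "Pre0_SS"


def classify_in_transcript(tx: Transcript, pos: int) -> str | None:
    """Region of a position within one transcript, or None if outside it."""
    if not tx.start <= pos <= tx.end:
        return None
    for ivs, label in ((tx.cds, "CDS"), (tx.utr3, "3'UTR"), (tx.utr5, "5'UTR")):
        if any(s <= pos <= e for s, e in ivs):
            return label
    if any(s <= pos <= e for s, e in tx.exons):
        return "noncoding-exon"
    return "intron"


def assign_genic_region(
    chrom: str,
    pos: int,
    tx_index: Mapping,
    precedence: Sequence[str] = REGION_PRECEDENCE,
) -> GenicAssignment:
    """Classify one site against all overlapping transcripts, then apply the
    precedence order across the per-transcript labels."""
    labels: dict[str, str] = {}
    genes: list[str] = []
    for tx in features_at(tx_index, chrom, pos):
        label = classify_in_transcript(tx, pos)
        if label is None:
            continue
        if tx.gene_id not in genes:
            genes.append(tx.gene_id)
        # keep the first transcript providing each label (deterministic:
        # interval trees are queried per site, transcripts sorted below)
        labels.setdefault(label, tx.transcript_id)
    if not labels:
        return GenicAssignment(chrom, pos, INTERGENIC, (), None)
    for region in precedence:
        if region in labels:
            return GenicAssignment(chrom, pos, region, tuple(genes), labels[region])
    # a label outside the configured precedence: fall back to any
    region = next(iter(labels))
    return GenicAssignment(chrom, pos, region, tuple(genes), labels[region])


def assign_genic_regions(
    sites: Iterable[tuple[str, int]],
    transcripts: Sequence[Transcript] | Mapping,
    precedence: Sequence[str] = REGION_PRECEDENCE,
) -> list[GenicAssignment]:
    index = (
        transcripts
        if isinstance(transcripts, Mapping)
        else build_transcript_index(transcripts)
    )
    return [assign_genic_region(c, p, index, precedence) for c, p in sites]


def intersect_repeats(
    sites: Iterable[tuple[str, int]],
    repeats: Sequence[RepeatFeature] | Mapping,
) -> list[RepeatAssignment]:
    """Repeat membership per site; longest containing interval wins."""
    index = repeats if isinstance(repeats, Mapping) else build_repeat_index(repeats)
    out = []
    for chrom, pos in sites:
        hits = features_at(index, chrom, pos)
        if not hits:
            out.append(RepeatAssignment(chrom, pos, False, None, None))
            continue
        best = min(hits, key=lambda r: (-(r.end - r.start), r.start, r.end, r.label))
        out.append(
            RepeatAssignment(chrom, pos, True, best.class_family, best.element)
        )
    return out


@dataclass
class AnnotationSummary:
    """Counts/percentages for regions (over all A-to-I sites), repeat
    residency (over all A-to-I sites), and class/element breakdowns (over
    repeat-resident sites)."""

    regions: pd.DataFrame
    repeat: pd.DataFrame
    repeat_classes: pd.DataFrame
    elements: pd.DataFrame
    n_sites: int


def summarize_annotation(
    genic: Sequence[GenicAssignment] | None = None,
    repeats: Sequence[RepeatAssignment] | None = None,
    *,
    region_counts: Mapping[str, int] | None = None,
    n_in_repeat: int | None = None,
    n_sites: int | None = None,
    class_counts: Mapping[str, int] | None = None,
    element_counts: Mapping[str, int] | None = None,
) -> AnnotationSummary:
    """Partition summaries, either from assignment lists or from plain counts
    (so published count tables run through the same arithmetic)."""
    if genic is not None:
        region_counts = {}
        for g in genic:
            region_counts[g.region] = region_counts.get(g.region, 0) + 1
        if n_sites is None:
            n_sites = len(genic)
    if repeats is not None:
        n_in_repeat = sum(1 for r in repeats if r.in_repeat)
        if n_sites is None:
            n_sites = len(repeats)
        class_counts = {}
        element_counts = {}
        for r in repeats:
            if r.in_repeat:
                class_counts[r.class_family] = class_counts.get(r.class_family, 0) + 1
                element_counts[r.element] = element_counts.get(r.element, 0) + 1
    n_sites = n_sites or 0

    regions = (
        share_table(region_counts, denominator=n_sites)
        if region_counts
        else pd.DataFrame(columns=["count", "percent"])
    )
    if n_in_repeat is not None and n_sites:
        repeat_df = share_table(
            {"repeat": n_in_repeat, "nonrepeat": n_sites - n_in_repeat},
            denominator=n_sites,
        )
    else:
        repeat_df = pd.DataFrame(columns=["count", "percent"])
    classes = (
        share_table(class_counts) if class_counts else pd.DataFrame(columns=["count", "percent"])
    )
    elements = (
        share_table(element_counts)
        if element_counts
        else pd.DataFrame(columns=["count", "percent"])
    )
    return AnnotationSummary(regions, repeat_df, classes, elements, n_sites)
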