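"""Editing-site calling: pileup, candidate rule, filter cascade, strand/type
resolution and the multi-tissue atlas.

The filter cascade mirrors the published screening: (1) coverage of at least
10 reads, (2) at least 3 reads supporting the variant, (3) editing rate of at
least 0.05 (denominator = total high-quality depth), (4) removal of all known
SNP positions (any allele). An optional external blacklist stands in for the
study's PCA-based per-tissue removal, whose procedure is not reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._stats import share_table
from .reference import features_at

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}


class AlignmentError(ValueError):
    """An alignment record is inconsistent with the reference."""


@dataclass(frozen=True)
class FilterThresholds:
    """Inclusive thresholds of the filter cascade; quality gates feed the
    pileup (the published pipeline delegates those to its caller)."""

    min_depth: int = 10
    min_alt_reads: int = 3
    min_rate: float = 0.05
    min_base_quality: int = 20
    min_mapping_quality: int = 20

    def __post_init__(self) -> None:
        if not self.min_depth >= self.min_alt_reads >= 1:
            raise ValueError("require min_depth >= min_alt_reads >= 1")
        if not 0 < self.min_rate <= 1:
            raise ValueError("min_rate must be in (0, 1]")


class PileupColumn(NamedTuple):
    chrom: str
    pos: int  # 1-based
    ref_base: str
    counts: tuple[int, int, int, int]  # A, C, G, T after quality gates
    depth: int


@dataclass(frozen=True)
class CandidateSite:
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    n_ref: int
    n_alt: int
    depth: int
    editing_level: float
    sample_id: str

    @property
    def mismatch_type(self) -> str:
        return f"{self.ref_base}-to-{self.alt_base}"


@dataclass(frozen=True)
class SiteCall:
    """A filtered, strand/type-resolved per-sample site (atlas fragment)."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    strand: str  # '+', '-' or '.'
    site_type: str  # "A-to-I" or a raw "X-to-Y" mismatch label
    editing_level: float
    depth: int
    n_alt: int
    sample_id: str


# ------------------------------------------------------------------ pileup


def pileup_counts(
    sam_path: str | Path,
    chrom_lengths: Mapping[str, int],
    thresholds: FilterThresholds,
) -> dict[str, np.ndarray]:
    """Base counts per position from a SAM file, as ``{chrom: (4, L) array}``.

    Secondary/supplementary/unmapped/duplicate records, reads below the
    mapping-quality gate and bases below the base-quality gate are excluded.
    """
    import pysam

    counts = {
        chrom: np.zeros((4, length), dtype=np.uint32)
        for chrom, length in chrom_lengths.items()
    }
    lut = np.full(256, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        lut[ord(base)] = code
        lut[ord(base.lower())] = code
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_duplicate or read.is_qcfail:
                continue
            if (read.mapping_quality or 0) < thresholds.min_mapping_quality:
                continue
            chrom = read.reference_name
            if chrom not in counts:
                raise AlignmentError(
                    f"read {read.query_name!r} maps to {chrom!r}, absent from "
                    "the reference"
                )
            seq = read.query_sequence
            if seq is None:
                continue
            codes = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
            quals = read.query_qualities
            qual_arr = (
                np.array(quals, dtype=np.int16)
                if quals is not None
                else np.full(len(seq), 255, dtype=np.int16)
            )
            arr = counts[chrom]
            cig = read.cigartuples or [(0, len(seq))]
            qoff = 0
            roff = read.reference_start
            for op, ln in cig:
                if op in (0, 7, 8):  # M, =, X
                    q = slice(qoff, qoff + ln)
                    keep = (qual_arr[q] >= thresholds.min_base_quality) & (
                        codes[q] < 4
                    )
                    if keep.any():
                        np.add.at(
                            arr,
                            (codes[q][keep], roff + np.nonzero(keep)[0]),
                            1,
                        )
                    qoff += ln
                    roff += ln
                elif op in (1, 4):  # I, S consume query
                    qoff += ln
                elif op in (2, 3):  # D, N consume reference
                    roff += ln
                # 5 (H), 6 (P) consume neither
    return counts


def iter_pileup_columns(
    counts: Mapping[str, np.ndarray],
    genome: Mapping[str, str],
    skip_pure_ref: bool = False,
) -> Iterator[PileupColumn]:
    """Stream non-empty pileup columns; optionally skip columns with no
    alternative allele at all (those can never yield a candidate)."""
    for chrom in counts:
        arr = counts[chrom]
        depth = arr.sum(axis=0)
        seq = genome[chrom]
        ref_codes = np.full(len(seq), 255, dtype=np.uint8)
        encoded = np.frombuffer(seq.encode(), dtype=np.uint8)
        for base, code in _CODE.items():
            ref_codes[encoded == ord(base)] = code
        if skip_pure_ref:
            safe_ref = np.where(ref_codes < 4, ref_codes, 0)
            ref_counts = arr[safe_ref, np.arange(arr.shape[1])]
            ref_counts = np.where(ref_codes < 4, ref_counts, 0)
            positions = np.nonzero(depth > ref_counts)[0]
        else:
            positions = np.nonzero(depth > 0)[0]
        for p0 in positions:
            col = arr[:, p0]
            yield PileupColumn(
                chrom,
                int(p0) + 1,
                seq[p0],
                (int(col[0]), int(col[1]), int(col[2]), int(col[3])),
                int(depth[p0]),
            )


def build_pileup(
    sam_path: str | Path,
    genome: Mapping[str, str],
    thresholds: FilterThresholds | None = None,
    skip_pure_ref: bool = False,
) -> Iterator[PileupColumn]:
    """Quality-gated pileup over a SAM file (convenience wrapper)."""
    thresholds = thresholds or FilterThresholds()
    counts = pileup_counts(
        sam_path, {c: len(s) for c, s in genome.items()}, thresholds
    )
    return iter_pileup_columns(counts, genome, skip_pure_ref=skip_pure_ref)


# ------------------------------------------------------------- candidates


def call_candidates(
    columns: Iterable[PileupColumn],
    sample_id: str = "sample",
    stats: dict | None = None,
) -> list[CandidateSite]:
    """Apply the single-alternative candidate rule to a pileup stream.

    A column yields a candidate when exactly one alternative base has >= 2
    supporting reads (other alternatives may have at most a stray singleton),
    or when a single alternative is present at all. Columns with two or more
    alternatives at >= 2 reads are multi-allelic and skipped (counted).
    """
    out: list[CandidateSite] = []
    n_multi = 0
    n_badref = 0
    for col in columns:
        ref = col.ref_base
        if ref not in _CODE:
            n_badref += 1
            continue
        ref_code = _CODE[ref]
        alt_counts = [
            (c, n) for c, n in enumerate(col.counts) if c != ref_code and n > 0
        ]
        strong = [(c, n) for c, n in alt_counts if n >= 2]
        if len(strong) >= 2:
            n_multi += 1
            continue
        if len(strong) == 1:
            alt_code, n_alt = strong[0]
        elif len(alt_counts) == 1:
            alt_code, n_alt = alt_counts[0]
        else:
            continue
        out.append(
            CandidateSite(
                chrom=col.chrom,
                pos=col.pos,
                ref_base=ref,
                alt_base=BASES[alt_code],
                n_ref=col.counts[ref_code],
                n_alt=n_alt,
                depth=col.depth,
                editing_level=n_alt / col.depth,
                sample_id=sample_id,
            )
        )
    if stats is not None:
        stats["multiallelic_skipped"] = n_multi
        stats["nonstandard_ref_skipped"] = n_badref
    if n_multi or n_badref:
        logger.info(
            "call_candidates: skipped %d multi-allelic and %d non-ACGT-ref columns",
            n_multi,
            n_badref,
        )
    return out


def apply_filters(
    candidates: Iterable[CandidateSite],
    thresholds: FilterThresholds,
    snp_positions: set[tuple[str, int]] | frozenset = frozenset(),
    blacklist: set[tuple[str, int]] | frozenset = frozenset(),
) -> list[CandidateSite]:
    """The cascade: depth >= 10, alt reads >= 3, rate >= 0.05 (all inclusive),
    known-SNP mask by position, optional external blacklist."""
    return [
        c
        for c in candidates
        if c.depth >= thresholds.min_depth
        and c.n_alt >= thresholds.min_alt_reads
        and c.editing_level >= thresholds.min_rate
        and (c.chrom, c.pos) not in snp_positions
        and (c.chrom, c.pos) not in blacklist
    ]


# --------------------------------------------------- strand/type resolution


def feature_strand(chrom: str, pos: int, tx_index, repeat_index) -> str:
    """Strand from an unambiguous overlapping gene, else repeat, else '.'."""
    for index, attr in ((tx_index, "strand"), (repeat_index, "strand")):
        if index is None:
            continue
        strands = {getattr(f, attr) for f in features_at(index, chrom, pos)}
        if len(strands) == 1:
            return strands.pop()
    return "."


def resolve_strand_type(
    cand: CandidateSite, tx_index=None, repeat_index=None
) -> SiteCall:
    """Resolve A-to-I identity: A>G on '+' evidence or T>C on '-' evidence.

    Contradictory combinations (e.g. A>G inside a minus-strand gene) and
    feature-less T>C/A>G sites keep their raw mismatch type with strand
    unknown, matching how unresolved conversions are reported separately.
    """
    strand = feature_strand(cand.chrom, cand.pos, tx_index, repeat_index)
    mism = (cand.ref_base, cand.alt_base)
    if mism == ("A", "G") and strand == "+":
        site_type, out_strand = "A-to-I", "+"
    elif mism == ("T", "C") and strand == "-":
        site_type, out_strand = "A-to-I", "-"
    else:
        site_type, out_strand = cand.mismatch_type, "."
    return SiteCall(
        chrom=cand.chrom,
        pos=cand.pos,
        ref_base=cand.ref_base,
        alt_base=cand.alt_base,
        strand=out_strand,
        site_type=site_type,
        editing_level=cand.editing_level,
        depth=cand.depth,
        n_alt=cand.n_alt,
        sample_id=cand.sample_id,
    )


# ----------------------------------------------------------------- atlas


def merge_atlas(
    calls_by_sample: Mapping[str, Sequence[SiteCall]],
    sample_tissue: Mapping[str, str],
    depth_by_sample: Mapping[str, Mapping[str, np.ndarray]] | None = None,
    min_depth: int = 10,
    tissues: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Merge per-sample calls into a sites x tissues atlas.

    A site enters the atlas if it passed the cascade in at least one sample.
    Two per-tissue statistics are kept: ``passed_level_<t>`` averages only the
    samples in which the site passed, while ``level_<t>`` averages all samples
    *covering* the site at ``min_depth`` (treating covered-but-not-passing
    samples as level 0, which is what makes strictly tissue-specific sites
    comparable across tissues). Without ``depth_by_sample`` coverage
    information, covered == passed and the two coincide.
    """
    if not calls_by_sample:
        raise ValueError("at least one sample is required")
    for sample in calls_by_sample:
        if sample not in sample_tissue:
            raise ValueError(f"sample {sample!r} has no tissue assignment")
    if tissues is None:
        seen = []
        for s in calls_by_sample:
            t = sample_tissue[s]
            if t not in seen:
                seen.append(t)
        tissues = seen

    keys: dict[tuple, SiteCall] = {}
    per_sample_level: dict[str, dict[tuple, float]] = {}
    for sample, calls in calls_by_sample.items():
        lv = {}
        for call in calls:
            key = (call.chrom, call.pos, call.ref_base, call.alt_base)
            lv[key] = call.editing_level
            keys.setdefault(key, call)
        per_sample_level[sample] = lv

    ordered = sorted(keys)
    rows = []
    for key in ordered:
        proto = keys[key]
        chrom, pos, ref, alt = key
        row = {
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "strand": proto.strand,
            "type": proto.site_type,
        }
        for tissue in tissues:
            samples = [s for s in calls_by_sample if sample_tissue[s] == tissue]
            passed = [
                per_sample_level[s][key] for s in samples if key in per_sample_level[s]
            ]
            if depth_by_sample is not None:
                covered_levels = []
                for s in samples:
                    depths = depth_by_sample.get(s, {})
                    arr = depths.get(chrom)
                    d = int(arr[pos - 1]) if arr is not None and pos - 1 < len(arr) else 0
                    if key in per_sample_level[s]:
                        covered_levels.append(per_sample_level[s][key])
                    elif d >= min_depth:
                        covered_levels.append(0.0)
            else:
                covered_levels = passed
            row[f"level_{tissue}"] = (
                float(np.mean(covered_levels)) if covered_levels else np.nan
            )
            row[f"passed_level_{tissue}"] = (
                float(np.mean(passed)) if passed else np.nan
            )
            row[f"n_passed_{tissue}"] = len(passed)
            row[f"n_covered_{tissue}"] = len(covered_levels)
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------- summaries


def type_counts(atlas: pd.DataFrame) -> dict[str, int]:
    return atlas["type"].value_counts().to_dict()


def summarize_types(
    counts: Mapping[str, int] | pd.DataFrame,
    strand_counts: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Counts and 1-decimal percentages per resolved mismatch type.

    Accepts either an atlas frame or a plain ``{type: count}`` mapping, so a
    published count table can be fed through the same arithmetic.
    """
    if isinstance(counts, pd.DataFrame):
        counts = type_counts(counts)
    table = share_table(counts)
    if strand_counts is not None:
        total = sum(strand_counts.values())
        a2i = counts.get("A-to-I", counts.get("A-to-G", 0))
        if total != a2i:
            raise ValueError(
                f"strand partition sums to {total}, expected the A-to-I total {a2i}"
            )
    return table


def strand_partition(atlas: pd.DataFrame) -> dict[str, int]:
    """Counts of A-to-I sites per resolved strand."""
    sub = atlas[atlas["type"] == "A-to-I"]
    return sub["strand"].value_counts().to_dict()
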