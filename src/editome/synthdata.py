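"""Synthetic reference bundle and tissue-structured read simulator.

Generates everything the editing-site caller downstream needs without any
external download: a random genome with a repeat track dominated by pig-style
SINE/tRNA elements (Pre0_SS, PRE1*), gene models with CDS/UTR/intron structure
on both strands, heterozygous SNP decoys, a truth table of planted A-to-I
sites with tissue-structured editing rates, ungapped aligned reads (SAM), and
designed miRNAs whose seed complements the edited or unedited 3'UTR allele.

Editing is planted in the unstranded-library convention: a plus-strand site is
a genomic A whose reads show G, a minus-strand site is a genomic T whose reads
show C. Heterozygous SNP decoys carry the same mismatch classes at ~0.5 allele
fraction so that only the SNP mask — not the coverage/rate filters — removes
them.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import (
    ReferenceBundle,
    RepeatFeature,
    Snp,
    Transcript,
    revcomp,
)

DEFAULT_TISSUES = (
    "brain",
    "liver",
    "adipose",
    "intestine",
    "heart",
    "skeletal_muscle",
    "lung",
)

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_A, _C, _G, _T = 0, 1, 2, 3

# repeat classes drawn with pig-editome-like weights: almost everything is a
# tRNA-derived SINE (PRE-1 family), a sliver of LINE/L1 and other elements
_REPEAT_CLASSES = (
    (("SINE", "tRNA"), 0.941),
    (("LINE", "L1"), 0.049),
    (("LTR", "ERV1"), 0.010),
)
_SINE_ELEMENTS = (
    ("Pre0_SS", 0.55),
    ("PRE1f", 0.20),
    ("PRE1f2", 0.10),
    ("PRE1e", 0.10),
    ("PRE1g", 0.05),
)

# transcript template, offsets within a gene span (0-based half-open);
# mirrored for minus-strand genes so both orientations carry all feature kinds
_EXONS = ((0, 1500), (2200, 2500), (3200, 3500), (4200, 4600))
_GENE_SPAN = 4600
_GENE_GAP = 3000


class ConfigError(ValueError):
    """The synthetic configuration is internally unsatisfiable."""


class SynthesisError(RuntimeError):
    """The genome cannot host the requested features."""


@dataclass
class SynthConfig:
    """Knobs of the synthetic study; defaults emulate the source data scale
    at desk size (repeat-resident site fraction 0.982, +1 G bias, 7 tissues,
    ~30x depth, 0.1% sequencing error)."""

    genome_length: int = 1_000_000
    n_chromosomes: int = 2
    gc_content: float = 0.42
    repeat_fraction_of_sites: float = 0.982
    repeat_genome_fraction: float = 0.35
    n_edit_sites: int = 2000
    tissue_names: tuple[str, ...] = DEFAULT_TISSUES
    per_tissue_edit_rate: dict[str, float] | None = None
    n_specific_sites: int = 70
    specific_rate: float = 0.4
    n_utr3_sites: int = 8
    n_snp_decoys: int = 200
    read_length: int = 100
    mean_depth: float = 30.0
    seq_error_rate: float = 0.001
    context_g_plus1_bias: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.per_tissue_edit_rate is None:
            self.per_tissue_edit_rate = {t: 0.2 for t in self.tissue_names}
        self.tissue_names = tuple(self.tissue_names)

    def validate(self) -> None:
        fractions = {
            "gc_content": self.gc_content,
            "repeat_fraction_of_sites": self.repeat_fraction_of_sites,
            "repeat_genome_fraction": self.repeat_genome_fraction,
            "seq_error_rate": self.seq_error_rate,
            "context_g_plus1_bias": self.context_g_plus1_bias,
            "specific_rate": self.specific_rate,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if not self.tissue_names:
            raise ConfigError("tissue_names must be non-empty")
        if len(set(self.tissue_names)) != len(self.tissue_names):
            raise ConfigError("tissue_names must be unique")
        for t in self.tissue_names:
            r = self.per_tissue_edit_rate.get(t)
            if r is None or not 0.0 <= r <= 1.0:
                raise ConfigError(f"per_tissue_edit_rate[{t}] must be in [0, 1]")
        if self.n_edit_sites < self.n_specific_sites:
            raise ConfigError("n_edit_sites must be >= n_specific_sites")
        if self.n_edit_sites < 0 or self.n_snp_decoys < 0:
            raise ConfigError("counts must be non-negative")
        per_chrom = self.genome_length // self.n_chromosomes
        if per_chrom < 2 * (_GENE_SPAN + _GENE_GAP) + 4 * self.read_length:
            raise ConfigError(
                "genome_length too small: each chromosome needs room for one "
                "gene per strand "
                f"(>= {2 * (_GENE_SPAN + _GENE_GAP) + 4 * self.read_length} bp "
                f"per chromosome, got {per_chrom})"
            )


def _rng(cfg: SynthConfig, *tags: int | str) -> np.random.Generator:
    """Deterministic child generator for one stage / sample."""
    entropy = [cfg.rng_seed & 0x7FFFFFFF]
    for tag in tags:
        if isinstance(tag, str):
            tag = zlib.crc32(tag.encode()) & 0x7FFFFFFF
        entropy.append(int(tag) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _encode(seq: str) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    for base, code in _CODE.items():
        lut[ord(base)] = code
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


_DECODE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _DECODE_LUT[codes].tobytes().decode()


# ------------------------------------------------------------ reference


def _make_transcript(idx: int, chrom: str, offset: int, strand: str) -> Transcript:
    exons = [(offset + s + 1, offset + e) for s, e in _EXONS]
    if strand == "+":
        # exon1 = 5'UTR (250) + CDS; exons 2-3 CDS; exon4 = 3'UTR
        utr5 = [(exons[0][0], exons[0][0] + 249)]
        cds = [(exons[0][0] + 250, exons[0][1]), exons[1], exons[2]]
        utr3 = [exons[3]]
    else:
        # genomic mirror: exon1 = 3'UTR; exons 2-3 CDS; exon4 = CDS + 5'UTR
        utr3 = [exons[0]]
        cds = [exons[1], exons[2], (exons[3][0], exons[3][1] - 150)]
        utr5 = [(exons[3][1] - 149, exons[3][1])]
    return Transcript(
        transcript_id=f"SYNT{idx:04d}",
        gene_id=f"SYNG{idx:04d}",
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds=cds,
        utr5=utr5,
        utr3=utr3,
    )


def _place_repeats(
    rng: np.random.Generator, chrom: str, length: int, fraction: float
) -> list[RepeatFeature]:
    if fraction <= 0:
        return []
    repeats = []
    class_weights = [w for _, w in _REPEAT_CLASSES]
    pos = int(rng.integers(0, 400))
    while pos < length:
        rclass, family = _REPEAT_CLASSES[int(rng.choice(len(_REPEAT_CLASSES), p=class_weights))][0]
        if rclass == "SINE":
            element = str(
                rng.choice(
                    [e for e, _ in _SINE_ELEMENTS], p=[w for _, w in _SINE_ELEMENTS]
                )
            )
            rep_len = int(rng.integers(180, 280))
        elif rclass == "LINE":
            element = "L1_SS"
            rep_len = int(rng.integers(1000, 4000))
        else:
            element = "ERV1_SS"
            rep_len = int(rng.integers(300, 600))
        gap = int(rng.exponential(rep_len * (1.0 - fraction) / fraction)) if fraction < 1 else 0
        start = pos + gap
        end = start + rep_len
        if end > length:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        repeats.append(RepeatFeature(chrom, start, end, rclass, family, element, strand))
        pos = end
    return repeats


def generate_reference(cfg: SynthConfig) -> ReferenceBundle:
    """Build a random genome with genes, repeats and heterozygous SNP decoys.

    Deterministic for a fixed ``cfg.rng_seed``; the same config written twice
    yields byte-identical files.
    """
    cfg.validate()
    rng = _rng(cfg, "reference")
    per_chrom = cfg.genome_length // cfg.n_chromosomes
    gc = cfg.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]

    genome: dict[str, str] = {}
    transcripts: list[Transcript] = []
    repeats: list[RepeatFeature] = []
    tx_idx = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        codes = rng.choice(4, size=per_chrom, p=probs).astype(np.uint8)
        genome[chrom] = _decode(codes)
        offset = 2 * cfg.read_length
        while offset + _GENE_SPAN + 2 * cfg.read_length <= per_chrom:
            strand = "+" if tx_idx % 2 == 0 else "-"
            transcripts.append(_make_transcript(tx_idx, chrom, offset, strand))
            tx_idx += 1
            offset += _GENE_SPAN + _GENE_GAP
        repeats.extend(
            _place_repeats(rng, chrom, per_chrom, cfg.repeat_genome_fraction)
        )

    # guarantee a repeat inside one 3'UTR per strand so UTR-resident,
    # repeat-resident sites always exist for the miRNA design stage
    if cfg.repeat_genome_fraction > 0:
        for strand in "+-":
            tx = next(t for t in transcripts if t.strand == strand)
            us, ue = tx.utr3[0]
            mid = (us + ue) // 2
            repeats.append(
                RepeatFeature(
                    tx.chrom, mid - 125, mid + 125, "SINE", "tRNA", "Pre0_SS", strand
                )
            )
    repeats.sort(key=lambda r: (r.chrom, r.start, r.end))

    snps = _place_snps(cfg, rng, genome)
    bundle = ReferenceBundle(genome, transcripts, repeats, snps)
    bundle.validate()
    return bundle


def _place_snps(
    cfg: SynthConfig, rng: np.random.Generator, genome: Mapping[str, str]
) -> list[Snp]:
    """Heterozygous A>G / T>C decoys: indistinguishable from editing except by
    the known-SNP mask."""
    snps: list[Snp] = []
    if cfg.n_snp_decoys == 0:
        return snps
    chroms = list(genome)
    taken: set[tuple[str, int]] = set()
    margin = cfg.read_length + 10
    attempts = 0
    while len(snps) < cfg.n_snp_decoys:
        attempts += 1
        if attempts > 200 * cfg.n_snp_decoys:
            raise SynthesisError(
                "not enough A/T positions to place the requested SNP decoys"
            )
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = len(genome[chrom])
        pos = int(rng.integers(margin, length - margin)) + 1
        base = genome[chrom][pos - 1]
        if base not in "AT" or (chrom, pos) in taken:
            continue
        taken.add((chrom, pos))
        alt = "G" if base == "A" else "C"
        snps.append(Snp(chrom, pos, base, alt))
    snps.sort(key=lambda s: (s.chrom, s.pos))
    return snps


# ------------------------------------------------------------ truth planting


TRUTH_COLUMNS = ("chrom", "pos", "strand", "in_repeat", "is_specific", "specific_tissue")


def plant_truth(ref: ReferenceBundle, cfg: SynthConfig) -> pd.DataFrame:
    """Plant A-to-I editing sites and return the truth table.

    Site strand follows the overlapping gene (else repeat, else the base
    itself), so the caller's strand resolution can recover it; the reference
    base on the annotated strand is always A. The strand-aware +1 neighbour is
    rewritten to G with probability ``context_g_plus1_bias`` (mutating
    ``ref.genome``), planting the ADAR-like context signature. No site
    coincides with a SNP decoy.
    """
    cfg.validate()
    rng = _rng(cfg, "truth")
    codes = {c: _encode(s).copy() for c, s in ref.genome.items()}
    snp_pos = {(s.chrom, s.pos) for s in ref.snps}

    masks = {}
    gene_strand = {}
    for chrom, arr in codes.items():
        in_rep = np.zeros(len(arr), dtype=bool)
        masks[chrom] = in_rep
        gs = np.zeros(len(arr), dtype=np.int8)
        gene_strand[chrom] = gs
    for rep in ref.repeats:
        masks[rep.chrom][rep.start : rep.end] = True
    rep_strand = {c: np.zeros(len(a), dtype=np.int8) for c, a in codes.items()}
    for rep in ref.repeats:
        rep_strand[rep.chrom][rep.start : rep.end] = 1 if rep.strand == "+" else -1
    for tx in ref.transcripts:
        gene_strand[tx.chrom][tx.start - 1 : tx.end] = 1 if tx.strand == "+" else -1

    margin = cfg.read_length + 10
    occupied = {c: np.zeros(len(a), dtype=bool) for c, a in codes.items()}

    def strand_at(chrom: str, p0: int) -> int:
        st = gene_strand[chrom][p0]
        if st == 0:
            st = rep_strand[chrom][p0]
        return int(st)

    def try_place(chrom: str, p0: int) -> str | None:
        arr = codes[chrom]
        if p0 < margin or p0 >= len(arr) - margin:
            return None
        if occupied[chrom][p0] or (chrom, p0 + 1) in snp_pos:
            return None
        base = arr[p0]
        if base not in (_A, _T):
            return None
        st = strand_at(chrom, p0)
        if st == 0:
            st = 1 if base == _A else -1
        if (st > 0 and base != _A) or (st < 0 and base != _T):
            return None
        occupied[chrom][max(0, p0 - 12) : p0 + 13] = True
        return "+" if st > 0 else "-"

    records: list[dict] = []

    def add_site(chrom: str, p0: int, strand: str, in_repeat: bool) -> None:
        records.append(
            {
                "chrom": chrom,
                "pos": p0 + 1,
                "strand": strand,
                "in_repeat": in_repeat,
                "is_specific": False,
                "specific_tissue": "",
            }
        )

    # 1) sites inside 3'UTRs, needed by the miRNA design stage
    utr_targets = []
    for tx in ref.transcripts:
        for s, e in tx.utr3:
            utr_targets.append((tx.chrom, s, e))
    n_utr = min(cfg.n_utr3_sites, cfg.n_edit_sites) if utr_targets else 0
    ui = 0
    placed_utr = 0
    utr_order = rng.permutation(len(utr_targets)) if utr_targets else np.array([], dtype=int)
    while placed_utr < n_utr and ui < 200 * max(1, n_utr):
        ui += 1
        chrom, s, e = utr_targets[int(utr_order[ui % len(utr_order)])]
        lo, hi = s - 1 + 25, e - 25  # 0-based candidate range, clear of UTR ends
        if hi <= lo:
            continue
        p0 = int(rng.integers(lo, hi))
        strand = try_place(chrom, p0)
        if strand is None:
            continue
        add_site(chrom, p0, strand, bool(masks[chrom][p0]))
        placed_utr += 1

    # 2) the remaining sites, repeat membership drawn per site
    pools = {}
    for chrom, arr in codes.items():
        at = (arr == _A) | (arr == _T)
        at[:margin] = False
        at[len(arr) - margin :] = False
        pools[chrom] = {
            True: rng.permutation(np.nonzero(at & masks[chrom])[0]),
            False: rng.permutation(np.nonzero(at & ~masks[chrom])[0]),
        }
    cursors = {c: {True: 0, False: 0} for c in codes}
    chrom_names = list(codes)

    def draw_from_pool(want_repeat: bool) -> tuple[str, int, str] | None:
        order = rng.permutation(len(chrom_names))
        for flag in (want_repeat, not want_repeat):
            for k in order:
                chrom = chrom_names[k]
                pool = pools[chrom][flag]
                cur = cursors[chrom][flag]
                while cur < len(pool):
                    p0 = int(pool[cur])
                    cur += 1
                    strand = try_place(chrom, p0)
                    if strand is not None:
                        cursors[chrom][flag] = cur
                        return chrom, p0, strand
                cursors[chrom][flag] = cur
        return None

    while len(records) < cfg.n_edit_sites:
        want = bool(rng.random() < cfg.repeat_fraction_of_sites)
        hit = draw_from_pool(want)
        if hit is None:
            raise SynthesisError(
                "not enough A/T positions satisfying spacing/margin constraints "
                f"to plant {cfg.n_edit_sites} sites"
            )
        chrom, p0, strand = hit
        add_site(chrom, p0, strand, bool(masks[chrom][p0]))

    truth = pd.DataFrame(records, columns=list(TRUTH_COLUMNS))

    # 3) tissue structure: flat background rates, single-tissue specific sites
    for t in cfg.tissue_names:
        truth[f"rate_{t}"] = cfg.per_tissue_edit_rate[t]
    if cfg.n_specific_sites > 0 and len(truth) > 0:
        candidates = truth.index[n_utr:] if len(truth) > n_utr else truth.index
        chosen = rng.choice(
            np.asarray(candidates), size=min(cfg.n_specific_sites, len(candidates)),
            replace=False,
        )
        for j, idx in enumerate(sorted(chosen)):
            tissue = cfg.tissue_names[j % len(cfg.tissue_names)]
            truth.loc[idx, "is_specific"] = True
            truth.loc[idx, "specific_tissue"] = tissue
            for t in cfg.tissue_names:
                truth.loc[idx, f"rate_{t}"] = (
                    cfg.specific_rate if t == tissue else 0.0
                )

    # 4) plant the +1 context bias (strand-aware downstream neighbour)
    other = {_A: [_C, _T], _C: [_A, _T], _G: [_A, _C, _T], _T: [_A, _C]}
    for rec in truth.itertuples():
        p0 = rec.pos - 1
        q0 = p0 + 1 if rec.strand == "+" else p0 - 1
        arr = codes[rec.chrom]
        if q0 < 0 or q0 >= len(arr) or (rec.chrom, q0 + 1) in snp_pos:
            continue
        if rng.random() < cfg.context_g_plus1_bias:
            arr[q0] = _G if rec.strand == "+" else _C
        else:
            # non-G on the site strand, uniform over A/C/T
            choice = int(rng.integers(3))
            plus_base = [_A, _C, _T][choice]
            arr[q0] = plus_base if rec.strand == "+" else [_T, _G, _A][choice]

    for chrom in codes:
        ref.genome[chrom] = _decode(codes[chrom])

    truth = truth.sort_values(["chrom", "pos"], ignore_index=True)
    return truth


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def load_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


# ------------------------------------------------------------ read simulation


def simulate_reads(
    ref: ReferenceBundle,
    truth: pd.DataFrame,
    tissue: str,
    sample_id: str,
    cfg: SynthConfig,
    out_sam: str | Path,
) -> Path:
    """Simulate ungapped aligned reads for one sample and write a SAM file.

    Per-position depth is ~Poisson(``mean_depth``); at a planted site reads
    carry the edited allele with probability equal to the tissue's true rate,
    SNP decoys are heterozygous (allele fraction 0.5), and uniform sequencing
    errors are applied last.
    """
    cfg.validate()
    if tissue not in cfg.tissue_names:
        raise ValueError(f"unknown tissue {tissue!r}; configured: {cfg.tissue_names}")
    import pysam

    rng = _rng(cfg, "reads", tissue, sample_id)
    rl = cfg.read_length
    rate_col = f"rate_{tissue}"

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": l} for c, l in ref.chrom_lengths.items()],
        "PG": [{"ID": "editome", "PN": "editome"}],
        "RG": [{"ID": sample_id, "SM": sample_id, "LB": tissue}],
    }
    out_sam = Path(out_sam)
    qual_list = [40] * rl
    offsets = np.arange(rl)
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as out:
        for tid, (chrom, seq) in enumerate(ref.genome.items()):
            length = len(seq)
            if cfg.mean_depth <= 0 or length < rl:
                continue
            n_starts = length - rl + 1
            n_reads = int(rng.poisson(cfg.mean_depth * n_starts / rl))
            if n_reads == 0:
                continue
            starts = np.sort(rng.integers(0, n_starts, size=n_reads))
            reads = _encode(seq)[starts[:, None] + offsets]

            def spike(pos1: int, alt_code: int, rate: float) -> None:
                p0 = pos1 - 1
                lo = np.searchsorted(starts, p0 - rl + 1, side="left")
                hi = np.searchsorted(starts, p0, side="right")
                if hi <= lo:
                    return
                rows = np.arange(lo, hi)
                edited = rng.random(len(rows)) < rate
                rows = rows[edited]
                reads[rows, p0 - starts[rows]] = alt_code

            for rec in truth[truth.chrom == chrom].itertuples():
                rate = getattr(rec, rate_col)
                if rate <= 0:
                    continue
                alt = _G if rec.strand == "+" else _C
                spike(rec.pos, alt, float(rate))
            for snp in ref.snps:
                if snp.chrom == chrom:
                    spike(snp.pos, _CODE[snp.alt], 0.5)

            if cfg.seq_error_rate > 0:
                err = rng.random(reads.shape) < cfg.seq_error_rate
                n_err = int(err.sum())
                if n_err:
                    shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                    reads[err] = (reads[err] + shift) % 4

            for i in range(n_reads):
                seg = pysam.AlignedSegment()
                seg.query_name = f"{sample_id}.{chrom}.{i}"
                seg.query_sequence = _decode(reads[i])
                seg.flag = 0
                seg.reference_id = tid
                seg.reference_start = int(starts[i])
                seg.mapping_quality = 60
                seg.cigartuples = [(0, rl)]
                seg.query_qualities = qual_list
                out.write(seg)
    return out_sam


# ------------------------------------------------------------ miRNA design


@dataclass
class MirnaDesign:
    """One designed miRNA (plus its shuffled control) targeting a 3'UTR site."""

    mirna_id: str
    control_id: str
    sequence: str  # RNA, 5'->3'
    control_sequence: str
    chrom: str
    pos: int
    transcript_id: str
    utr_offset: int  # 0-based offset of the edited base within the 3'UTR
    designed_allele: str  # "A" (unedited) or "G" (edited)


def utr3_sequence(tx: Transcript, genome: Mapping[str, str]) -> str:
    """3'UTR sequence in transcript orientation (5'->3')."""
    parts = [genome[tx.chrom][s - 1 : e] for s, e in tx.utr3]
    seq = "".join(parts)
    return revcomp(seq) if tx.strand == "-" else seq


def utr3_offset(tx: Transcript, pos: int) -> int | None:
    """Offset of a genomic position within the transcript-oriented 3'UTR."""
    off = 0
    raw = None
    for s, e in tx.utr3:
        if s <= pos <= e:
            raw = off + (pos - s)
        off += e - s + 1
    if raw is None:
        return None
    return raw if tx.strand == "+" else off - 1 - raw


def sites_in_utr3(
    ref: ReferenceBundle, truth: pd.DataFrame
) -> list[tuple[pd.Series, Transcript, int]]:
    hits = []
    for _, row in truth.iterrows():
        for tx in ref.transcripts:
            if tx.chrom != row.chrom or tx.strand != row.strand:
                continue
            off = utr3_offset(tx, int(row.pos))
            if off is not None:
                hits.append((row, tx, off))
                break
    return hits


def generate_mirnas(
    ref: ReferenceBundle,
    truth: pd.DataFrame,
    cfg: SynthConfig,
    mirna_length: int = 22,
) -> list[MirnaDesign]:
    """Design miRNAs against planted 3'UTR sites.

    The whole miRNA is the reverse complement of a window of the chosen
    allele, with the edited base paired inside the seed (miRNA position 5);
    designs alternate between the unedited (A) and edited (G) allele. Each
    design gets a shuffled control with no perfect seed match to either
    allele's +/-150 bp window.
    """
    cfg.validate()
    rng = _rng(cfg, "mirnas")
    utr_sites = sites_in_utr3(ref, truth)
    if not utr_sites:
        raise SynthesisError("no planted editing site falls inside a 3'UTR")

    # the miRNA pairs positions 1..L against window indices L-1..0; placing the
    # edit at seed position 5 puts it at window index L-5 of an L-mer segment
    seed_pos = 5
    designs: list[MirnaDesign] = []
    for i, (row, tx, off) in enumerate(utr_sites):
        utr = utr3_sequence(tx, ref.genome)
        left = mirna_length - seed_pos
        if off - left < 0 or off + seed_pos > len(utr):
            continue
        segment = utr[off - left : off + seed_pos]
        if segment[left] != "A":
            raise SynthesisError(
                f"3'UTR site {row.chrom}:{row.pos} is not A in transcript orientation"
            )
        allele = "A" if i % 2 == 0 else "G"
        if allele == "G":
            segment = segment[:left] + "G" + segment[left + 1 :]
        mirna_dna = revcomp(segment)
        win_lo, win_hi = max(0, off - 150), off + 151
        window_a = utr[win_lo:win_hi]
        window_g = (
            window_a[: off - win_lo] + "G" + window_a[off - win_lo + 1 :]
        )
        control = _shuffled_control(rng, mirna_dna, (window_a, window_g))
        suffix = "unedited" if allele == "A" else "edited"
        designs.append(
            MirnaDesign(
                mirna_id=f"syn-miR-{i + 1:03d}-{suffix}",
                control_id=f"syn-miR-{i + 1:03d}-{suffix}-ctrl",
                sequence=mirna_dna.replace("T", "U"),
                control_sequence=control.replace("T", "U"),
                chrom=str(row.chrom),
                pos=int(row.pos),
                transcript_id=tx.transcript_id,
                utr_offset=off,
                designed_allele=allele,
            )
        )
    if not designs:
        raise SynthesisError("no 3'UTR site had enough flanking UTR sequence")
    return designs


def _shuffled_control(
    rng: np.random.Generator, mirna_dna: str, windows: tuple[str, str]
) -> str:
    for _ in range(500):
        perm = rng.permutation(len(mirna_dna))
        shuffled = "".join(mirna_dna[j] for j in perm)
        seed_rc = revcomp(shuffled[1:8])
        if all(seed_rc not in w for w in windows):
            return shuffled
    raise SynthesisError("could not shuffle a seed-match-free control miRNA")


def write_mirna_fasta(designs: Iterable[MirnaDesign], path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in designs:
            fh.write(
                f">{d.mirna_id} target={d.chrom}:{d.pos} allele={d.designed_allele}\n"
            )
            fh.write(d.sequence + "\n")
            fh.write(f">{d.control_id} control_of={d.mirna_id}\n")
            fh.write(d.control_sequence + "\n")


def design_table(designs: Iterable[MirnaDesign]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": d.mirna_id,
                "control_id": d.control_id,
                "sequence": d.sequence,
                "control_sequence": d.control_sequence,
                "chrom": d.chrom,
                "pos": d.pos,
                "transcript_id": d.transcript_id,
                "utr_offset": d.utr_offset,
                "designed_allele": d.designed_allele,
            }
            for d in designs
        ]
    )
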