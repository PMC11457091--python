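"""Reference data model: genome sequences, gene models, repeats, known SNPs.

Coordinate conventions, fixed package-wide and enforced here:

* site positions and GTF features are **1-based inclusive**;
* BED intervals are **0-based half-open**;
* a 1-based position ``p`` intersects a BED interval ``[s, e)`` iff ``s < p <= e``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from intervaltree import IntervalTree

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class MalformedAnnotationError(ValueError):
    """A transcript violates its own structure (e.g. CDS outside exons)."""


@dataclass(frozen=True)
class Snp:
    """A known polymorphism; masking is by position only, any allele."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str


@dataclass(frozen=True)
class RepeatFeature:
    """One repeat-masker style interval, BED 0-based half-open."""

    chrom: str
    start: int
    end: int
    repeat_class: str  # e.g. "SINE"
    family: str  # e.g. "tRNA"
    element: str  # e.g. "Pre0_SS"
    strand: str = "+"

    @property
    def class_family(self) -> str:
        return f"{self.repeat_class}/{self.family}"

    @property
    def label(self) -> str:
        return f"{self.repeat_class}/{self.family}/{self.element}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    """A transcript model with 1-based inclusive exon/CDS/UTR intervals."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        self.utr5 = sorted(self.utr5)
        self.utr3 = sorted(self.utr3)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def validate(self) -> None:
        if self.strand not in "+-":
            raise MalformedAnnotationError(
                f"{self.transcript_id}: strand must be + or -"
            )
        if not self.exons:
            raise MalformedAnnotationError(f"{self.transcript_id}: no exons")
        for (s1, e1), (s2, e2) in itertools.pairwise(self.exons):
            if e1 >= s2:
                raise MalformedAnnotationError(
                    f"{self.transcript_id}: overlapping exons ({s1},{e1}) ({s2},{e2})"
                )
        for kind, ivs in (("CDS", self.cds), ("5'UTR", self.utr5), ("3'UTR", self.utr3)):
            for s, e in ivs:
                if not any(xs <= s and e <= xe for xs, xe in self.exons):
                    raise MalformedAnnotationError(
                        f"{self.transcript_id}: {kind} interval ({s},{e}) outside exons"
                    )

    def derive_utrs(self) -> None:
        """Fill UTR intervals from exon minus CDS when the source lacked UTR lines."""
        if not self.cds or (self.utr5 or self.utr3):
            return
        cds_lo = self.cds[0][0]
        cds_hi = self.cds[-1][1]
        left, right = [], []
        for s, e in self.exons:
            if s < cds_lo:
                left.append((s, min(e, cds_lo - 1)))
            if e > cds_hi:
                right.append((max(s, cds_hi + 1), e))
        if self.strand == "+":
            self.utr5, self.utr3 = left, right
        else:
            self.utr5, self.utr3 = right, left


@dataclass
class ReferenceBundle:
    """Self-contained stand-in for a genome + annotation release.

    ``genome`` maps chromosome name to an upper-case sequence string;
    ``transcripts`` / ``repeats`` / ``snps`` follow the conventions above.
    """

    genome: dict[str, str]
    transcripts: list[Transcript]
    repeats: list[RepeatFeature]
    snps: list[Snp]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def base_at(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.genome[chrom][pos - 1]

    def validate(self) -> None:
        lengths = self.chrom_lengths
        for tx in self.transcripts:
            tx.validate()
            if tx.end > lengths[tx.chrom] or tx.start < 1:
                raise MalformedAnnotationError(
                    f"{tx.transcript_id}: outside chromosome bounds"
                )
        for rep in self.repeats:
            if rep.start < 0 or rep.end > lengths[rep.chrom]:
                raise MalformedAnnotationError(f"repeat {rep} outside bounds")

    # ------------------------------------------------------------------ I/O
    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "genes": outdir / "genes.gtf",
            "repeats": outdir / "repeats.bed",
            "snps": outdir / "snps.vcf",
        }
        write_genome_fasta(self.genome, paths["genome"])
        write_gtf(self.transcripts, paths["genes"])
        write_repeats_bed(self.repeats, paths["repeats"])
        write_snps_vcf(self.snps, self.chrom_lengths, paths["snps"])
        return paths

    @classmethod
    def load(
        cls,
        genome_fasta: str | Path,
        gtf: str | Path | None = None,
        repeats_bed: str | Path | None = None,
        snps_vcf: str | Path | None = None,
    ) -> "ReferenceBundle":
        genome = load_genome_fasta(genome_fasta)
        transcripts = load_gtf(gtf) if gtf else []
        repeats = load_repeats_bed(repeats_bed) if repeats_bed else []
        snps = load_snps_vcf(snps_vcf) if snps_vcf else []
        bundle = cls(genome, transcripts, repeats, snps)
        bundle.validate()
        return bundle


# ---------------------------------------------------------------- writers


def write_genome_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gtf(transcripts: Iterable[Transcript], path: str | Path) -> None:
    feature_lists = {
        "exon": "exons",
        "CDS": "cds",
        "five_prime_utr": "utr5",
        "three_prime_utr": "utr3",
    }
    with open(path, "w") as fh:
        fh.write("#!genome-build synthetic\n")
        for tx in transcripts:
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            gene_attrs = f'gene_id "{tx.gene_id}";'
            fh.write(
                f"{tx.chrom}\teditome\tgene\t{tx.start}\t{tx.end}\t.\t{tx.strand}\t.\t{gene_attrs}\n"
            )
            fh.write(
                f"{tx.chrom}\teditome\ttranscript\t{tx.start}\t{tx.end}\t.\t{tx.strand}\t.\t{attrs}\n"
            )
            for feat, attr in feature_lists.items():
                for s, e in getattr(tx, attr):
                    frame = "0" if feat == "CDS" else "."
                    fh.write(
                        f"{tx.chrom}\teditome\t{feat}\t{s}\t{e}\t.\t{tx.strand}\t{frame}\t{attrs}\n"
                    )


def write_repeats_bed(repeats: Iterable[RepeatFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rep in repeats:
            fh.write(
                f"{rep.chrom}\t{rep.start}\t{rep.end}\t{rep.label}\t0\t{rep.strand}\n"
            )


def write_snps_vcf(
    snps: Iterable[Snp], chrom_lengths: Mapping[str, int], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=editome\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for snp in snps:
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t.\t{snp.ref}\t{snp.alt}\t.\tPASS\t.\n"
            )


# ---------------------------------------------------------------- readers


def load_genome_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_gtf(path: str | Path) -> list[Transcript]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts = []
    for t in db.features_of_type("transcript"):
        kw = {}
        for feat, attr in (
            ("exon", "exons"),
            ("CDS", "cds"),
            ("five_prime_utr", "utr5"),
            ("three_prime_utr", "utr3"),
        ):
            kw[attr] = [(f.start, f.end) for f in db.children(t, featuretype=feat)]
        tx = Transcript(
            transcript_id=t.attributes["transcript_id"][0],
            gene_id=t.attributes["gene_id"][0],
            chrom=t.seqid,
            strand=t.strand,
            **kw,
        )
        tx.derive_utrs()
        tx.validate()
        transcripts.append(tx)
    return transcripts


def load_repeats_bed(path: str | Path) -> list[RepeatFeature]:
    repeats = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "repeat/unknown/unknown"
            strand = fields[5] if len(fields) > 5 else "+"
            parts = name.split("/")
            while len(parts) < 3:
                parts.append("unknown")
            repeats.append(
                RepeatFeature(chrom, start, end, parts[0], parts[1], parts[2], strand)
            )
    return repeats


def load_snps_vcf(path: str | Path) -> list[Snp]:
    import pysam

    snps = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else "."
            snps.append(Snp(rec.chrom, rec.pos, rec.ref, alt))
    return snps


# ------------------------------------------------------------- interval indexes


def build_transcript_index(transcripts: Iterable[Transcript]) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree over transcript spans (0-based half-open)."""
    trees: dict[str, IntervalTree] = {}
    for tx in transcripts:
        trees.setdefault(tx.chrom, IntervalTree()).addi(tx.start - 1, tx.end, tx)
    return trees


def build_repeat_index(repeats: Iterable[RepeatFeature]) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree over repeat intervals (native BED coords)."""
    trees: dict[str, IntervalTree] = {}
    for rep in repeats:
        trees.setdefault(rep.chrom, IntervalTree()).addi(rep.start, rep.end, rep)
    return trees


def features_at(trees: Mapping[str, IntervalTree], chrom: str, pos: int) -> list:
    """Payloads of intervals containing a 1-based position."""
    tree = trees.get(chrom)
    if tree is None:
        return []
    return [iv.data for iv in tree.at(pos - 1)]
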