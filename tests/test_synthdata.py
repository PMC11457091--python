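"""Generator invariants: determinism, composition targets, planted truth."""

import numpy as np
import pysam
import pytest

from editome import annotate as ann
from editome import synthdata as syn
from editome.reference import ReferenceBundle, revcomp


def test_reference_is_byte_deterministic(tmp_path):
    cfg = syn.SynthConfig(genome_length=40_000, n_chromosomes=1, n_edit_sites=40,
                          n_specific_sites=7, n_snp_decoys=10, rng_seed=3)
    outs = []
    for name in ("a", "b"):
        cfg2 = syn.SynthConfig(**{**cfg.__dict__})
        ref = syn.generate_reference(cfg2)
        truth = syn.plant_truth(ref, cfg2)
        d = tmp_path / name
        ref.write(d)
        syn.write_truth(truth, d / "truth.tsv")
        syn.simulate_reads(ref, truth, cfg2.tissue_names[0], "s1", cfg2, d / "s1.sam")
        outs.append(d)
    for fname in ("genome.fa", "genes.gtf", "repeats.bed", "snps.vcf", "truth.tsv", "s1.sam"):
        assert (outs[0] / fname).read_bytes() == (outs[1] / fname).read_bytes()


def test_gc_content_matches_config():
    cfg = syn.SynthConfig(genome_length=200_000, n_chromosomes=1, gc_content=0.42,
                          n_edit_sites=0, n_specific_sites=0, n_snp_decoys=0, rng_seed=5)
    ref = syn.generate_reference(cfg)
    seq = "".join(ref.genome.values())
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert abs(gc - 0.42) < 0.01


def test_zero_repeat_track_is_valid():
    cfg = syn.SynthConfig(genome_length=40_000, n_chromosomes=1,
                          repeat_genome_fraction=0.0, n_edit_sites=20,
                          n_specific_sites=0, n_snp_decoys=0, rng_seed=2)
    ref = syn.generate_reference(cfg)
    assert ref.repeats == []
    truth = syn.plant_truth(ref, cfg)
    assert not truth.in_repeat.any()


def test_zero_sites_gives_empty_truth():
    cfg = syn.SynthConfig(genome_length=40_000, n_chromosomes=1, n_edit_sites=0,
                          n_specific_sites=0, n_snp_decoys=5, n_utr3_sites=0, rng_seed=2)
    ref = syn.generate_reference(cfg)
    truth = syn.plant_truth(ref, cfg)
    assert len(truth) == 0


@pytest.mark.parametrize(
    "kwargs, fragment",
    [
        ({"gc_content": 1.5}, "gc_content"),
        ({"tissue_names": ()}, "tissue_names"),
        ({"tissue_names": ("liver", "liver")}, "unique"),
        ({"n_edit_sites": 2, "n_specific_sites": 5}, "n_specific_sites"),
        ({"genome_length": 5_000}, "genome_length too small"),
    ],
)
def test_config_validation_names_the_constraint(kwargs, fragment):
    cfg = syn.SynthConfig(**kwargs)
    with pytest.raises(syn.ConfigError, match=fragment):
        cfg.validate()


def test_truth_invariants(small_bundle, small_cfg):
    ref, truth = small_bundle
    snp_keys = {(s.chrom, s.pos) for s in ref.snps}
    for rec in truth.itertuples():
        base = ref.base_at(rec.chrom, rec.pos)
        # reference base reads A on the annotated editing strand
        assert (base, rec.strand) in {("A", "+"), ("T", "-")}
        assert (rec.chrom, rec.pos) not in snp_keys
    spec_rows = truth[truth.is_specific]
    assert len(spec_rows) == small_cfg.n_specific_sites
    rate_cols = [f"rate_{t}" for t in small_cfg.tissue_names]
    for rec in spec_rows.itertuples():
        rates = [getattr(rec, c) for c in rate_cols]
        assert sum(r > 0 for r in rates) == 1
        assert getattr(rec, f"rate_{rec.specific_tissue}") == small_cfg.specific_rate


def test_repeat_fraction_of_sites_within_binomial_tolerance(small_bundle, small_cfg):
    ref, truth = small_bundle
    f = small_cfg.repeat_fraction_of_sites
    n = len(truth)
    sd = np.sqrt(f * (1 - f) / n)
    assert abs(truth.in_repeat.mean() - f) <= 3 * sd + 1e-12


def test_planted_plus_one_context_bias(small_bundle, small_cfg):
    ref, truth = small_bundle
    plus1_g = []
    for rec in truth.itertuples():
        if rec.strand == "+":
            nb = ref.base_at(rec.chrom, rec.pos + 1)
        else:
            nb = revcomp(ref.base_at(rec.chrom, rec.pos - 1))
        plus1_g.append(nb == "G")
    bias = small_cfg.context_g_plus1_bias
    sd = np.sqrt(bias * (1 - bias) / len(plus1_g))
    assert abs(np.mean(plus1_g) - bias) <= 3 * sd


def test_truth_flags_survive_file_roundtrip(small_bundle, small_cfg, tmp_path):
    """Re-reading the emitted FASTA/GTF/BED/VCF reproduces repeat membership."""
    ref, truth = small_bundle
    paths = ref.write(tmp_path)
    loaded = ReferenceBundle.load(
        paths["genome"], paths["genes"], paths["repeats"], paths["snps"]
    )
    assert loaded.chrom_lengths == ref.chrom_lengths
    sites = list(zip(truth.chrom, truth.pos))
    rep = ann.intersect_repeats(sites, loaded.repeats)
    assert [r.in_repeat for r in rep] == list(truth.in_repeat)
    for rec in truth.itertuples():
        assert loaded.base_at(rec.chrom, rec.pos) == ref.base_at(rec.chrom, rec.pos)


def test_simulated_allele_fractions_and_depth(tmp_path):
    cfg = syn.SynthConfig(genome_length=30_000, n_chromosomes=1, n_edit_sites=20,
                          n_specific_sites=0, n_snp_decoys=10, n_utr3_sites=2,
                          mean_depth=200, rng_seed=13)
    ref = syn.generate_reference(cfg)
    truth = syn.plant_truth(ref, cfg)
    sam = tmp_path / "s.sam"
    syn.simulate_reads(ref, truth, "brain", "s", cfg, sam)

    counts = {c: np.zeros((4, l), dtype=int) for c, l in ref.chrom_lengths.items()}
    code = {b: i for i, b in enumerate("ACGT")}
    n_reads = 0
    with pysam.AlignmentFile(str(sam), "r") as fh:
        for read in fh:
            n_reads += 1
            arr = counts[read.reference_name]
            for off, base in enumerate(read.query_sequence):
                arr[code[base], read.reference_start + off] += 1
    assert n_reads > 0

    rate = cfg.per_tissue_edit_rate["brain"]
    for rec in truth.itertuples():
        arr = counts[rec.chrom][:, rec.pos - 1]
        depth = arr.sum()
        alt = arr[code["G"]] if rec.strand == "+" else arr[code["C"]]
        sd = np.sqrt(rate * (1 - rate) / depth)
        assert abs(alt / depth - rate) <= 3 * sd + 0.01  # +0.01 absorbs seq error

    # SNP decoys are heterozygous
    for snp in ref.snps:
        arr = counts[snp.chrom][:, snp.pos - 1]
        frac = arr[code[snp.alt]] / arr.sum()
        assert 0.35 < frac < 0.65

    # interior coverage averages to mean_depth within 5%
    chrom = next(iter(counts))
    interior = counts[chrom].sum(axis=0)[cfg.read_length : -cfg.read_length]
    assert abs(interior.mean() - cfg.mean_depth) / cfg.mean_depth < 0.05


def test_zero_depth_gives_header_only_sam(small_bundle, tmp_path):
    ref, truth = small_bundle
    cfg = syn.SynthConfig(genome_length=60_000, n_chromosomes=2, mean_depth=0.0,
                          n_edit_sites=10, n_specific_sites=0, rng_seed=1)
    sam = tmp_path / "empty.sam"
    syn.simulate_reads(ref, truth, "liver", "s", cfg, sam)
    with pysam.AlignmentFile(str(sam), "r") as fh:
        assert sum(1 for _ in fh) == 0


def test_unknown_tissue_raises(small_bundle, small_cfg, tmp_path):
    ref, truth = small_bundle
    with pytest.raises(ValueError, match="unknown tissue"):
        syn.simulate_reads(ref, truth, "kidney", "s", small_cfg, tmp_path / "x.sam")


def test_designed_mirna_seed_complements_chosen_allele(small_bundle, small_cfg):
    ref, truth = small_bundle
    designs = syn.generate_mirnas(ref, truth, small_cfg)
    assert {d.designed_allele for d in designs} == {"A", "G"}
    for d in designs:
        tx = next(t for t in ref.transcripts if t.transcript_id == d.transcript_id)
        utr = syn.utr3_sequence(tx, ref.genome)
        assert utr[d.utr_offset] == "A"
        mirna_dna = d.sequence.replace("U", "T")
        seed_rc = revcomp(mirna_dna[1:8])  # target 7-mer paired by positions 2-8
        window_a = utr[max(0, d.utr_offset - 20) : d.utr_offset + 21]
        center = d.utr_offset - max(0, d.utr_offset - 20)
        window_g = window_a[:center] + "G" + window_a[center + 1 :]
        if d.designed_allele == "A":
            assert seed_rc in window_a and seed_rc not in window_g
        else:
            assert seed_rc in window_g and seed_rc not in window_a
        # shuffled control: no perfect seed match against either allele
        ctrl_rc = revcomp(d.control_sequence.replace("U", "T")[1:8])
        lo, hi = max(0, d.utr_offset - 150), d.utr_offset + 151
        big_a = utr[lo:hi]
        big_g = big_a[: d.utr_offset - lo] + "G" + big_a[d.utr_offset - lo + 1 :]
        assert ctrl_rc not in big_a and ctrl_rc not in big_g


def test_mirna_generation_requires_utr_sites():
    cfg = syn.SynthConfig(genome_length=40_000, n_chromosomes=1, n_edit_sites=0,
                          n_specific_sites=0, n_utr3_sites=0, n_snp_decoys=0, rng_seed=4)
    ref = syn.generate_reference(cfg)
    truth = syn.plant_truth(ref, cfg)
    with pytest.raises(syn.SynthesisError, match="3'UTR"):
        syn.generate_mirnas(ref, truth, cfg)
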