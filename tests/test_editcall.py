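"""Pileup, candidate rule, filter cascade, strand resolution, atlas merge."""

import numpy as np
import pandas as pd
import pysam
import pytest

from editome import editcall as ec
from editome.reference import (
    RepeatFeature,
    Transcript,
    build_repeat_index,
    build_transcript_index,
    revcomp,
)

BASES = "ACGT"


def write_sam(path, chrom_lengths, reads):
    """reads: (chrom, start0, seq, quals, mapq, flag) tuples."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": c, "LN": l} for c, l in chrom_lengths.items()],
    }
    names = list(chrom_lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, (chrom, start, seq, quals, mapq, flag) in enumerate(reads):
            seg = pysam.AlignedSegment()
            seg.query_name = f"r{i}"
            seg.query_sequence = seq
            seg.flag = flag
            seg.reference_id = names.index(chrom)
            seg.reference_start = start
            seg.mapping_quality = mapq
            seg.cigartuples = [(0, len(seq))]
            seg.query_qualities = quals
            out.write(seg)


def brute_force_pileup(genome, reads, min_bq, min_mapq):
    counts = {c: np.zeros((4, len(s)), dtype=int) for c, s in genome.items()}
    for chrom, start, seq, quals, mapq, flag in reads:
        if flag & 0x904 or mapq < min_mapq:  # unmapped/secondary/supplementary
            continue
        for off, (base, q) in enumerate(zip(seq, quals)):
            if q >= min_bq and base in BASES:
                counts[chrom][BASES.index(base), start + off] += 1
    return counts


def test_pileup_matches_bruteforce_random_stack(tmp_path):
    rng = np.random.default_rng(42)
    genome = {"chr1": "".join(rng.choice(list(BASES), size=300))}
    reads = []
    for _ in range(10):
        start = int(rng.integers(0, 250))
        seq = "".join(rng.choice(list(BASES), size=50))
        quals = [int(q) for q in rng.integers(2, 41, size=50)]
        mapq = int(rng.choice([0, 10, 30, 60]))
        flag = int(rng.choice([0, 0, 0, 0x100, 0x800]))
        reads.append(("chr1", start, seq, quals, mapq, flag))
    sam = tmp_path / "stack.sam"
    write_sam(sam, {"chr1": 300}, reads)
    t = ec.FilterThresholds()
    counts = ec.pileup_counts(sam, {"chr1": 300}, t)
    expected = brute_force_pileup(genome, reads, t.min_base_quality, t.min_mapping_quality)
    assert np.array_equal(counts["chr1"], expected["chr1"])


def test_pileup_base_quality_gate(tmp_path):
    genome = {"chr1": "A" * 50}
    quals = [40] * 10
    quals[3] = 5  # below the gate
    reads = [("chr1", 0, "G" * 10, quals, 60, 0)]
    sam = tmp_path / "q.sam"
    write_sam(sam, {"chr1": 50}, reads)
    cols = list(ec.build_pileup(sam, genome))
    depth_at = {c.pos: c.depth for c in cols}
    assert depth_at[1] == 1 and 4 not in depth_at  # position 4 excluded entirely


def test_pileup_unknown_chromosome_errors(tmp_path):
    sam = tmp_path / "bad.sam"
    write_sam(sam, {"chrX": 100}, [("chrX", 0, "ACGT", [40] * 4, 60, 0)])
    with pytest.raises(ec.AlignmentError, match="chrX"):
        ec.pileup_counts(sam, {"chr1": 100}, ec.FilterThresholds())


def brute_force_candidate(col):
    """Independent statement of the single-alternative rule."""
    ref_code = BASES.index(col.ref_base)
    alts = [(c, n) for c, n in enumerate(col.counts) if c != ref_code and n > 0]
    strong = [a for a in alts if a[1] >= 2]
    if len(strong) >= 2:
        return None
    if len(strong) == 1:
        alt_code, n_alt = strong[0]
    elif len(alts) == 1:
        alt_code, n_alt = alts[0]
    else:
        return None
    return BASES[alt_code], n_alt


def test_candidate_rule_examples_and_random_oracle():
    col = ec.PileupColumn("chr1", 10, "A", (27, 0, 3, 0), 30)
    (cand,) = ec.call_candidates([col])
    assert (cand.alt_base, cand.n_alt, cand.editing_level) == ("G", 3, 0.1)

    multi = ec.PileupColumn("chr1", 11, "A", (20, 5, 5, 0), 30)
    stats = {}
    assert ec.call_candidates([multi], stats=stats) == []
    assert stats["multiallelic_skipped"] == 1

    rng = np.random.default_rng(0)
    cols = []
    for i in range(1000):
        counts = tuple(int(c) for c in rng.integers(0, 6, size=4))
        if sum(counts) == 0:
            continue
        cols.append(ec.PileupColumn("chr1", i + 1, BASES[int(rng.integers(4))], counts, sum(counts)))
    got = {(c.pos, c.alt_base, c.n_alt) for c in ec.call_candidates(cols)}
    want = set()
    for col in cols:
        res = brute_force_candidate(col)
        if res:
            want.add((col.pos, res[0], res[1]))
    assert got == want


def make_cand(depth=30, n_alt=6, chrom="chr1", pos=100, ref="A", alt="G"):
    return ec.CandidateSite(chrom, pos, ref, alt, depth - n_alt, n_alt, depth,
                            n_alt / depth, "s")


def test_filter_cascade_boundaries():
    t = ec.FilterThresholds()
    keep = make_cand(depth=10, n_alt=3)  # level 0.3: at every boundary
    assert ec.apply_filters([keep], t) == [keep]
    low_rate = make_cand(depth=100, n_alt=3)  # level 0.03
    assert ec.apply_filters([low_rate], t) == []
    shallow = make_cand(depth=9, n_alt=3)
    assert ec.apply_filters([shallow], t) == []
    few_alt = make_cand(depth=40, n_alt=2)
    assert ec.apply_filters([few_alt], t) == []
    at_snp = make_cand(depth=30, n_alt=15)
    assert ec.apply_filters([at_snp], t, snp_positions={("chr1", 100)}) == []
    blacklisted = make_cand(depth=30, n_alt=15)
    assert ec.apply_filters([blacklisted], t, blacklist={("chr1", 100)}) == []


def test_filter_monotonicity_in_all_thresholds():
    rng = np.random.default_rng(1)
    cands = []
    for i in range(400):
        depth = int(rng.integers(1, 60))
        n_alt = int(rng.integers(1, depth + 1))
        cands.append(make_cand(depth=depth, n_alt=n_alt, pos=i))
    grid_depth = [1, 5, 10, 20, 40]
    grid_alt = [1, 2, 3, 5]
    grid_rate = [0.01, 0.05, 0.1, 0.5]

    def n_kept(d, a, r):
        if not d >= a >= 1:
            return None
        t = ec.FilterThresholds(min_depth=d, min_alt_reads=a, min_rate=r)
        return len(ec.apply_filters(cands, t))

    for a in grid_alt:
        for r in grid_rate:
            kept = [n_kept(d, a, r) for d in grid_depth if n_kept(d, a, r) is not None]
            assert kept == sorted(kept, reverse=True)
    for d in grid_depth:
        for r in grid_rate:
            kept = [n_kept(d, a, r) for a in grid_alt if n_kept(d, a, r) is not None]
            assert kept == sorted(kept, reverse=True)
    for d in grid_depth:
        for a in grid_alt:
            kept = [n_kept(d, a, r) for r in grid_rate if n_kept(d, a, r) is not None]
            assert kept == sorted(kept, reverse=True)


@pytest.fixture(scope="module")
def tiny_annotation():
    txs = [
        Transcript("T+", "G+", "chr1", "+", exons=[(100, 200)]),
        Transcript("T-", "G-", "chr1", "-", exons=[(300, 400)]),
    ]
    reps = [RepeatFeature("chr1", 500, 600, "SINE", "tRNA", "Pre0_SS", "-")]
    return build_transcript_index(txs), build_repeat_index(reps)


def test_strand_and_type_resolution(tiny_annotation):
    txi, rpi = tiny_annotation
    a2g_plus = make_cand(pos=150)
    call = ec.resolve_strand_type(a2g_plus, txi, rpi)
    assert (call.site_type, call.strand) == ("A-to-I", "+")

    t2c_minus = make_cand(pos=350, ref="T", alt="C")
    call = ec.resolve_strand_type(t2c_minus, txi, rpi)
    assert (call.site_type, call.strand) == ("A-to-I", "-")

    t2c_nowhere = make_cand(pos=1000, ref="T", alt="C")
    call = ec.resolve_strand_type(t2c_nowhere, txi, rpi)
    assert (call.site_type, call.strand) == ("T-to-C", ".")

    a2g_in_minus_gene = make_cand(pos=350)  # contradictory combination
    call = ec.resolve_strand_type(a2g_in_minus_gene, txi, rpi)
    assert (call.site_type, call.strand) == ("A-to-G", ".")

    t2c_in_minus_repeat = make_cand(pos=550, ref="T", alt="C")
    call = ec.resolve_strand_type(t2c_in_minus_repeat, txi, rpi)
    assert (call.site_type, call.strand) == ("A-to-I", "-")


def make_call(chrom, pos, level, sample, ref="A", alt="G"):
    return ec.SiteCall(chrom, pos, ref, alt, "+", "A-to-I", level, 30,
                       max(1, int(level * 30)), sample)


def test_atlas_merge_examples():
    calls = {"s1": [make_call("chr1", 10, 0.1, "s1")],
             "s2": [make_call("chr1", 10, 0.3, "s2")]}
    atlas = ec.merge_atlas(calls, {"s1": "liver", "s2": "liver"})
    assert len(atlas) == 1
    assert atlas.loc[0, "passed_level_liver"] == pytest.approx(0.2)
    assert atlas.loc[0, "level_liver"] == pytest.approx(0.2)

    single = ec.merge_atlas({"s1": calls["s1"]}, {"s1": "liver"})
    assert single.loc[0, "level_liver"] == pytest.approx(0.1)

    with pytest.raises(ValueError, match="tissue"):
        ec.merge_atlas(calls, {"s1": "liver"})


def test_atlas_merge_matches_bruteforce_over_many_samples():
    rng = np.random.default_rng(3)
    tissues = ["brain", "liver", "lung"]
    positions = list(range(100, 130))
    calls, tissue_of = {}, {}
    for k in range(50):
        sid = f"s{k}"
        tissue_of[sid] = tissues[k % 3]
        sample_calls = []
        for pos in positions:
            if rng.random() < 0.6:
                sample_calls.append(make_call("chr1", pos, float(rng.random()), sid))
        calls[sid] = sample_calls
    atlas = ec.merge_atlas(calls, tissue_of)
    for _, row in atlas.iterrows():
        for tissue in tissues:
            levels = [
                c.editing_level
                for sid, cs in calls.items()
                if tissue_of[sid] == tissue
                for c in cs
                if c.pos == row["pos"]
            ]
            expect = np.mean(levels) if levels else np.nan
            got = row[f"passed_level_{tissue}"]
            if np.isnan(expect):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect)
            assert row[f"n_passed_{tissue}"] == len(levels)


def test_atlas_coverage_aware_levels():
    """A covered-but-unedited tissue reads as level 0, not missing."""
    depth = {"s1": {"chr1": np.full(200, 30)}, "s2": {"chr1": np.full(200, 30)}}
    calls = {"s1": [make_call("chr1", 10, 0.4, "s1")], "s2": []}
    atlas = ec.merge_atlas(calls, {"s1": "brain", "s2": "liver"}, depth, min_depth=10)
    row = atlas.iloc[0]
    assert row["level_brain"] == pytest.approx(0.4)
    assert row["level_liver"] == pytest.approx(0.0)
    assert np.isnan(row["passed_level_liver"])
    assert row["n_covered_liver"] == 1 and row["n_passed_liver"] == 0


def test_type_summary_percentages_and_conservation():
    atlas = pd.DataFrame({
        "type": ["A-to-I"] * 60 + ["T-to-C"] * 30 + ["C-to-T"] * 10,
        "strand": ["+"] * 40 + ["-"] * 20 + ["."] * 40,
    })
    summary = ec.summarize_types(atlas)
    assert summary["count"].sum() == len(atlas)
    assert summary.loc["A-to-I", "percent"] == 60.0
    single = ec.summarize_types({"A-to-I": 5})
    assert single.loc["A-to-I", "percent"] == 100.0
    strands = ec.strand_partition(atlas)
    assert sum(strands.values()) == 60


def test_mirror_symmetry_of_calling(tmp_path):
    """Reverse-complementing genome, annotation and reads swaps strands/types
    consistently: the A-to-I site stays A-to-I on the opposite strand."""
    rng = np.random.default_rng(9)
    length = 400
    genome = "".join(rng.choice(list(BASES), size=length))
    pos0 = 150  # 0-based site
    genome = genome[:pos0] + "A" + genome[pos0 + 1 :]
    tx = Transcript("T1", "G1", "chr1", "+", exons=[(101, 300)])

    def run(genome_seq, transcripts, reads):
        sam = tmp_path / f"m{rng.integers(1e9)}.sam"
        write_sam(sam, {"chr1": length}, reads)
        cols = ec.build_pileup(sam, {"chr1": genome_seq}, skip_pure_ref=True)
        cands = ec.call_candidates(cols)
        kept = ec.apply_filters(cands, ec.FilterThresholds())
        txi = build_transcript_index(transcripts)
        return [ec.resolve_strand_type(c, txi, {}) for c in kept]

    reads = []
    for i in range(20):
        start = pos0 - 50
        seq = list(genome[start : start + 100])
        if i < 8:
            seq[50] = "G"  # edited reads
        reads.append(("chr1", start, "".join(seq), [40] * 100, 60, 0))
    fwd = run(genome, [tx], reads)
    assert len(fwd) == 1 and fwd[0].site_type == "A-to-I" and fwd[0].strand == "+"

    # mirror the whole scenario
    rc_genome = revcomp(genome)
    rc_tx = Transcript("T1", "G1", "chr1", "-",
                       exons=[(length - 300 + 1, length - 101 + 1)])
    rc_reads = []
    for chrom, start, seq, quals, mapq, flag in reads:
        new_start = length - (start + len(seq))
        rc_reads.append((chrom, new_start, revcomp(seq), quals, mapq, flag))
    rev = run(rc_genome, [rc_tx], rc_reads)
    assert len(rev) == 1
    assert rev[0].site_type == "A-to-I" and rev[0].strand == "-"
    assert rev[0].pos == length - fwd[0].pos + 1
    assert rev[0].editing_level == pytest.approx(fwd[0].editing_level)
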