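# editome

A tested, reusable pipeline for profiling adenosine-to-inosine (A-to-I) RNA
editing from aligned RNA-seq reads, built around the analysis design used for
large pig (*Sus scrofa*) editome atlases: call candidate editing sites from
quality-gated pileups, apply a strict filter cascade with a known-SNP mask,
characterise the sites (genic region, repeat element, flanking sequence
context), detect tissue-specific editing sites by Shannon entropy, and rescan
edited vs unedited 3′UTR windows for gained or lost miRNA binding. A
first-class synthetic-data module generates a self-contained reference bundle
(genome FASTA, GTF gene models, a SINE-dominated repeat BED, a SNP VCF),
tissue-structured aligned reads with planted editing truth, and designed
miRNAs — so the whole pipeline runs and is validated without any download.

## Who this is for

Researchers analysing RNA editomes in species dominated by SINE
retrotransposon editing (the pig PRE-1/Pre0_SS analog of primate Alu
editing), and anyone who needs a deterministic, oracle-tested re-implementation
of the standard editome filter cascade rather than a black-box caller.

## The method

**Calling and filtering.** Reads below mapping quality 20, bases below base
quality 20 and secondary/supplementary/duplicate records are excluded from
the pileup. A column with reference base `R` yields a candidate `R>V` when a
single alternative allele is supported (multi-allelic columns are discarded);
the editing level is `n_alt / depth`. A candidate is retained when, inclusively,

```
depth ≥ 10   and   n_alt ≥ 3   and   n_alt/depth ≥ 0.05   and   site ∉ known SNPs
```

An optional external blacklist hook removes additional per-tissue site lists.
In unstranded libraries an A-to-I event appears as A>G on the transcribed
strand and T>C on the opposite genomic strand, so strand is resolved from an
unambiguous overlapping gene (else repeat): A>G on `+` or T>C on `−` becomes
A-to-I; everything else keeps its raw mismatch type. Per-sample calls merge
into a sites × tissues atlas of mean editing levels.

**Annotation and context.** Genic regions are assigned by interval
intersection with precedence CDS > 3′UTR > 5′UTR > noncoding-exon > intron
(no overlap = intergenic); repeat membership uses the BED half-open
convention (1-based site `p` hits `[s, e)` iff `s < p ≤ e`, longest interval
wins). The ±5 bp strand-aware context of every A-to-I site feeds a 4 × 11
column-normalised frequency matrix, which recovers the ADAR signature (G
enriched at +1, depleted at −1).

**Tissue specificity (ROKU-style).** For a site's editing-level vector *x*
over the 7 tissues (brain, liver, adipose, intestine, heart, skeletal muscle,
lung), a one-step Tukey biweight location estimate *b* (c = 5, ε = 1e−4)
centres the vector, `x′_i = |x_i − b|`, `p_i = x′_i / Σ x′`, and

```
H = − Σ p_i log2 p_i        (flat vectors: H ≡ log2 n)
```

Sites with H < 0.5 bits are tissue-specific editing sites (SES), assigned to
the argmax tissue of x′.

**Editing-aware miRNA rescan.** For a 3′UTR editing site, two windows of
±150 bp are built that differ only at the edited base (A vs G). Each window
is scanned with a fully specified miRanda-style local duplex aligner (miRNA
threaded 3′→5′; Watson–Crick +5, G:U wobble +2, mismatch −4, gaps −9/−4,
miRNA seed positions 2–8 doubled; hit threshold 140). A (site, miRNA) pair is
classified `lost_by_editing`, `gained_by_editing`, `retained` or `absent`
from hits covering the edited position — the in-silico analog of an editing
event in a seed-pairing region abolishing repression of the unedited allele.

## Worked example

```
cat > demo.yaml <<'YAML'
synth:
  genome_length: 60000
  n_chromosomes: 2
  n_edit_sites: 150
  n_specific_sites: 21
  n_snp_decoys: 30
  n_utr3_sites: 6
YAML
editome run-all --config demo.yaml --outdir demo_run --seed 1
```

This simulates a 60 kb two-chromosome genome with 150 planted A-to-I sites
(98.2% targeted at repeats, editing rate 0.2, 21 single-tissue sites at rate
0.4, 30 heterozygous SNP decoys), one 30× sample per tissue, then runs every
stage and prints the report (abridged):

```
"n_atlas_sites": 150,
"planted_sensitivity": 1.0,
"n_snp_positions_called": 0,
"type_percent": {"A-to-I": 100.0},
"a2i_strand_counts": {"+": 77, "-": 73},
"repeat_percent": {"repeat": 98.0, "nonrepeat": 2.0},
"context_g_plus1": 0.473, "context_g_minus1": 0.227,
"n_ses": 21,
"ses_per_tissue": {"adipose": 3, "brain": 3, "heart": 3, "intestine": 3,
                   "liver": 3, "lung": 3, "skeletal_muscle": 3},
"rescan_status_counts": {"absent": 24, "gained_by_editing": 12,
                         "lost_by_editing": 12}
```

Reading it: all 150 planted sites pass the cascade in at least one tissue
while none of the 30 SNP decoys survive the mask; the called strand split is
roughly even, 98% of called sites sit in repeats, and the planted +1 G
context bias (0.5) is recovered against the −1 background (0.23). All 21
planted single-tissue sites fall below the 0.5-bit entropy threshold and are
assigned to the correct tissue (3 per tissue). Every miRNA designed against
the unedited allele loses its site upon editing, every edited-allele design
gains one, and all 24 shuffled controls stay absent. Stage outputs
(`atlas.tsv`, `annotation.tsv`, `context_matrix.tsv`, `ses.tsv`,
`rescan.tsv`, `report.json`) land in `demo_run/`; individual stages are also
exposed as `editome simulate|call|annotate|context|ses|mirna-rescan` on
files.

## Layout

- `src/editome/synthdata.py` — reference bundle, truth planting, read
  simulator, miRNA designer
- `src/editome/editcall.py` — pileup, candidate rule, filter cascade, atlas
- `src/editome/annotate.py` — genic/repeat interval annotation
- `src/editome/context.py` — flanking-base frequency matrix
- `src/editome/specificity.py` — Tukey biweight, entropy, SES detection
- `src/editome/mirnascan.py` — allele windows, duplex aligner, rescan
- `src/editome/pipeline.py`, `src/editome/cli.py` — orchestration and the
  `editome` command
- `docs/methods.md` — model assumptions, parameter choices, limitations
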