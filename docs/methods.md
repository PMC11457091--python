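# Methods

## Scope and model

The package re-implements a bulk RNA-seq editome analysis as a deterministic,
testable pipeline. The object of study is A-to-I editing: ADAR enzymes
deaminate adenosine in double-stranded RNA, and since inosine is read as
guanosine, editing appears in unstranded sequencing data as A>G mismatches on
the plus genomic strand and T>C on the minus strand. The pipeline therefore
treats "A-to-I" as a *resolved* label: a raw A>G (T>C) mismatch becomes
A-to-I only when an unambiguous overlapping feature places the site on the
`+` (`−`) strand. Contradictory or feature-less sites keep their raw
mismatch label — which is why atlases report a residual T-to-C class next to
the dominant A-to-G class.

## Filter cascade

Candidates come from quality-gated pileups (base quality ≥ 20, mapping
quality ≥ 20 by default; both configurable because upstream callers differ
and rarely document their gates). The cascade retains a candidate when
`depth ≥ 10`, `n_alt ≥ 3`, `n_alt/depth ≥ 0.05`, and the position is not a
known SNP; all thresholds are inclusive ("at least"). Deliberate choices:

- **Editing-level denominator** is total high-quality depth (`n_alt/depth`),
  not `n_alt/(n_ref+n_alt)`. This matches the coverage wording of the depth
  filter and is conservative (never larger than the alternative).
- **SNP masking is positional**, any allele. Editing and polymorphism cannot
  be distinguished without matched DNA, so any known variant position is
  suspect.
- **Multi-allelic columns** (two or more alternatives with ≥ 2 reads each)
  are discarded and counted: deamination produces one alternative allele;
  multiple strong alternatives indicate mapping artefacts.
- **Atlas inclusion** requires passing in at least one sample.
- The PCA-based per-tissue removal step used in some published pipelines has
  no reproducible specification; `apply_filters` instead accepts an external
  blacklist of (chrom, pos) sites as a hook.

## Atlas merging and the two per-tissue means

The atlas keeps two statistics per tissue. `passed_level_<t>` is the mean
editing level over samples in which the site passed the cascade.
`level_<t>` is the mean over samples *covering* the site at the depth
threshold, with covered-but-not-passing samples contributing level 0. The
second statistic exists because tissue-specificity needs a defined value in
unedited tissues: a site edited only in skeletal muscle has no passing liver
sample, yet its liver editing level is genuinely ~0, not missing. Entropy is
computed on `level_<t>`; `passed_level_<t>` is reported for atlas-style
summaries. Without coverage information the two coincide.

## Tissue specificity

The specificity statistic follows the ROKU approach: centre the per-tissue
vector with a one-step Tukey biweight location estimate (median start,
MAD scale, `u_i = (x_i − m)/(c·s + ε)` with `c = 5`, `ε = 1e−4`, weights
`(1 − u²)²` inside |u| < 1, median returned when all weights vanish), take
absolute residuals, normalise to probabilities, and compute Shannon entropy
in bits. The biweight constants and the flat-vector convention
(`H ≡ log2 n`, maximally nonspecific) are stated here so the implementation
is self-contained and oracle-testable. SES are rows with `H < 0.5` strictly;
the 0.5-bit threshold is on the log2 scale the statistic is defined on.
Detection requires completeness across the 7 tissues (brain, liver, adipose,
intestine, heart, skeletal muscle, lung); incomplete rows are dropped and
counted. The assigned tissue is the argmax of the processed vector — a
deterministic replacement for AIC-based outlier selection; ties are all
listed and flagged.

## Annotation

Coordinate conventions are fixed package-wide: sites and GTF are 1-based
inclusive, BED is 0-based half-open, and a 1-based site `p` intersects
`[s, e)` iff `s < p ≤ e`. Genic precedence across transcripts is
CDS > 3′UTR > 5′UTR > noncoding-exon > intron (configurable; consequence
orderings differ between annotation tools and this one favours the regions
the analysis cares about — coding impact first, then the miRNA-relevant
3′UTR). Overlapping repeats resolve to the longest containing interval,
ties to the first in sorted order. Element percentages are reported with
repeat-resident sites as the denominator.

## Sequence context

Contexts are ±5 bp, strand-aware (minus-strand sites reverse-complemented so
the edited base reads A at the centre). Sites closer than the flank to a
chromosome end are dropped rather than N-padded — padding would dilute the
frequency columns; the dropped count is logged. The matrix is
column-normalised; a per-position `log2(freq/0.25)` enrichment accompanies
it for reporting.

## miRNA rescan

The duplex scorer is a deliberately fully specified miRanda-style scheme, not
a bit-for-bit reproduction of any release: local Gotoh alignment of the
miRNA (3′→5′) against the window (5′→3′) with Watson–Crick +5, G:U wobble
+2, mismatch −4, gap open −9, gap extend −4; contributions at miRNA seed
positions 2–8 (substitutions and miRNA-consuming gaps) are doubled; hits are
non-overlapping local maxima with score ≥ 140 (the conventional default),
extracted best-first with footprint masking. No free-energy filter is
applied — the score threshold is the single gate, configurable. A 22-nt
perfect duplex scores 5·15 + 10·7 = 145; editing a seed-paired A to G turns
a doubled match into a doubled U:G wobble, 145 → 139, which is what drops a
designed site below threshold and produces the lost/gained contrast.
Classification uses only hits covering the edited position; other hits in
the window are reported but cannot drive a gain/loss call. Windows are
±150 nt around the site in the transcript-oriented 3′UTR and truncate at UTR
ends (allele windows always have equal length).

## Synthetic data: what it emulates, what it does not

The generator plants the study conditions the pipeline is meant to recover:

- genome GC fraction 0.42 (pig-like), default 1 Mb over 2 chromosomes;
- a repeat track dominated by tRNA-derived SINEs (Pre0_SS, PRE1f, PRE1f2,
  PRE1e, PRE1g; plus LINE/L1 and a sliver of LTR) covering ~35% of the
  genome, with 98.2% of planted sites targeted at repeats;
- gene models with 5′UTR/CDS/intron/3′UTR structure on both strands;
- editing rate 0.2 per tissue (atlas-typical "10–20%" levels), single-tissue
  sites at rate 0.4 in one of the 7 tissues and 0 elsewhere;
- a +1 G / strand-aware context bias of 0.5 at planted sites;
- heterozygous SNP decoys (allele fraction 0.5) that pass every
  coverage/rate filter and are removable only by the SNP mask;
- ~Poisson(30) depth, 100 nt ungapped reads, uniform 0.1% sequencing error;
- designed miRNAs whose 22-nt sequence is the reverse complement of one
  allele's 3′UTR window with the edit paired at seed position 5, plus
  shuffled seed-match-free controls.

Not emulated (and therefore not demonstrated by passing tests): splice-aware
reads, indels, PCR duplicates, realistic quality-score profiles, reference
bias, double-stranded-RNA structure driving ADAR targeting, and
hyper-edited reads. Real-data performance on those axes is out of scope; the
synthetic results validate the *logic* of calling, filtering, specificity
and rescan, not aligner robustness.

## Problem sizes and numerical choices

The recovery experiments use a 1 Mb genome with 5,000 planted sites at 30×
over two samples. Two samples is the minimal analog of an atlas that merges
many runs per tissue: with editing rate 0.2 the per-sample chance that a
site attracts fewer than 3 supporting reads is ≈ P(Poisson(6) ≤ 2) ≈ 6%, so
single-sample sensitivity sits near 94% while the two-sample union exceeds
99%. The false-positive rate is measured on an unedited 1 Mb genome, where
three identical sequencing errors in one column are expected ≈ 0.45 times
per sample. Entropy oracles agree to 1e−9; alignment oracles to 1e−9 on
instances up to 60 nt. All randomness flows from one integer seed through
named child generators (stage, tissue, sample), making every emitted file
byte-reproducible.

## Known limitations

- Strand resolution trusts annotation; antisense transcription can
  misassign strands, inflating the raw T-to-C class.
- `plant_truth` rewrites +1 neighbours in place, so the reference FASTA must
  be written *after* planting (the pipeline does this).
- The candidate rule tolerates one stray singleton alternative next to a
  strong alternative; at extreme depth this slightly relaxes the
  multi-allelic exclusion.
- The duplex scorer's absolute scores are not comparable to any specific
  miRanda release; only the allele contrast (hit vs no hit) is meaningful.
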