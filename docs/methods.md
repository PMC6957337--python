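# Methods

`toxta` models and analyses a competence-regulated type II toxin-antitoxin
(TA) operon of the *Haemophilus influenzae* kind: a toxin CDS (*toxT*,
119 codons + stop) followed by an antitoxin CDS (*toxA*, 98 codons + stop),
transcribed from a CRP-S promoter 34 nt upstream of the toxin start and
from an internal, antitoxin-repressed promoter ("P2") whose transcripts
begin 30 nt inside the toxin CDS.  This note records the models, the
tunable parameters and their defaults, what the synthetic data do and do
not emulate, and the numerical choices a maintainer would want to know.

## Reference locus

The packaged reference is a synthetic 2600-nt locus constructed
deterministically (fixed construction seed) at H. influenzae-like base
composition (~38% GC).  It is not a copy of any real genome sequence; it
is built to *encode the constraints the analyses exercise*:

* CDS geometry — toxT at [800, 1160), toxA at [1166, 1463); CRP-S promoter
  point at 766 (34 nt upstream of the toxT start); P2 TSS at 830 (+30);
  flanking anchor genes at [240, 540) and [1700, 2000); analysis window =
  2300 nt centered on toxA.
* Translatability of the truncated transcript — the toxT codons are
  sampled so that the only in-frame ATG downstream of P2 ends 30 bp before
  the gene end, the first GTG downstream of +30 sits at +35, and neither
  has an AGGAGG-like Shine-Dalgarno within 5-13 nt spacing, while the real
  toxT start does (a canonical AGGAGG at −11).  Transcripts from P2 are
  therefore scored nonfunctional for toxin production, the regulatory
  point of the internal promoter.
* Natural alleles — fixed deletion intervals of 178 nt (toxT-internal,
  downstream of P2), 306 nt (covering both promoters and the toxT start),
  and 1015 nt (both CDSs, anchors intact) with an 87-nt novel replacement
  whose terminal bases are forced to differ from the flanking reference
  bases, so the breakpoints are unambiguous and the deletion/insert
  lengths are exact, not representation-dependent.
* Engineered strains — ΔtoxA excises the antitoxin CDS (promoters intact);
  ΔtoxT removes [810, 1155) (keeps the start codon, deletes P2 and
  position +100); ΔtoxTA removes everything past the first 150 nt of the
  operon (keeps P2); Δcrp and Δsxy leave the locus untouched and act only
  through promoter activity.

The published cohort composition is packaged as {intact: 20,
toxT-internal: 97, promoter-spanning: 45, whole-operon: 19} = 181 genomes,
162 of them with a recognizable antitoxin gene.  The primary counts (181
total, 162 recognizable, 97/45/19 per deletion) are internally consistent
only with 20 intact genomes, so 20 is used; the source material reports
slightly conflicting intact counts.

## Cohort simulator and the selection scheme

Each simulated genome is the reference window with one allele's
deletion/replacement applied, followed by independent point substitutions:
every site mutates with probability *d* (the "divergence" attempt rate) to
a uniformly chosen different base.  Inside the antitoxin CDS, proposals
are screened: changes creating stop codons are rejected outright and
nonsynonymous changes are accepted with probability ω (default ω = 0.037,
the antitoxin's estimated dN/dS).  Two independently mutated genomes
differ per neutral site with probability 2d(1−d) + (2/3)d², the closed
form the divergence test checks.

This acceptance-rejection scheme is deliberately simple.  It interacts
with the NG86 estimator in a known way: rejected nonsynonymous proposals
leave their sites unchanged rather than redrawing, and multiple-hit
corrections assume time-reversible noise, so the recovered ω is mildly
biased downward (measured ≈ 0.032 on average for a true 0.037 at pairwise
distance 0.1, n = 20 — well inside the 50% recovery tolerance the
estimator is held to).  An attempt rate of 0.23/site gives the target
mean pairwise distance of ~0.1 on the antitoxin CDS under this scheme.

## Allele classification

Scanning is anchor-based: both orientations of a genome are searched by
local alignment (match +1, mismatch −1, gap open −8, extend −0.5) for the
two flanking anchors (hit = identity ≥ 0.90 over ≥ 80% of the anchor) and
for the antitoxin CDS ("recognizable" = identity ≥ 0.70 over ≥ 60% of its
length — stricter than a cross-species homolog filter because these are
within-species comparisons).  With a recognizable toxA the window is the
2300 nt centered on it; otherwise the inter-anchor span.

The window is aligned globally to the reference window with the same
scores.  End gaps are penalized: with free end gaps, truncating the
alignment at a long deletion can outscore paying the gap, which silently
drops the downstream flank.  The aligned columns are segmented by rolling
identity (window 21, threshold 0.6; gap columns are failures), and
internal failing runs separated by fewer than 30 matched columns are
merged — the 87-nt novel replacement aligns by chance for 10-20 columns
inside the 1015-nt gap and must not split the event in two.  Run
boundaries are then refined by exact-match walks from both flanks,
constrained to contiguous query coordinates so chance matches of novel
sequence glued against the gap are not absorbed into the flanks.  The
largest refined run ≥ 30 nt (the minimum deletion size; the natural
alleles are ≥ 178 nt, and 30 nt separates alleles from indel noise) is
the deletion; query bases consumed inside it are the novel-insert length.
Class assignment is by feature overlap with precedence
whole-operon > promoter-spanning > toxT-internal; anything else, or
multiple runs, is `novel`.

On noise-free cohorts classification and lengths are exact; at 5%
divergence class agreement on 200 genomes is 100% in the packaged test.

## Read simulator

Transcript molecules are Poisson draws per isoform:

* full isoform, CRP-S TSS → operon 3′ end (transcript end 1470):
  rate = basal (50) × induction(t) × genotype modifier.  Induction is
  (1, 1.5, 10, 10) at t = (0, 10, 30, 100) min; Δcrp and Δsxy pin
  induction at 1.
* truncated isoform, P2 TSS → 3′ end: time-invariant, genotype-dependent —
  repressed 2.0 (wildtype, ΔtoxT, Δcrp, Δsxy), derepressed 508.78 (ΔtoxA),
  attenuated 0.762 with a 0.381 modifier on CRP-S output (ΔtoxTA).

The derepressed and attenuated values are not free: they are solved by
`calibrate_promoters` so that (i) the *expected normalized toxT fragment
count* of ΔtoxA at t = 0 is exactly 9× wildtype, and (ii) expected
normalized coverage at operon position +100 at t = 30 in ΔtoxTA is exactly
1/3 of wildtype.  The expectation integrates over the insert-size
distribution, so it accounts for the different transcript geometries of
the strain constructs (a ΔtoxA transcript is ~300 nt shorter than
wildtype, which changes where fragment midpoints fall).  Median-of-ratios
normalization cancels the total-mass denominator exactly in expectation,
which is what makes this calibration closed-form.

A background gene set (63 genes in operons across the CRP-S, CRP-N, purR,
tryptophan, tRNA, ribosomal and housekeeping classes, including the
gyrase/topoisomerase and SOS controls) provides the rest of the
transcriptome.  Baselines and fold-change profiles are balanced so total
transcript mass is approximately conserved across the time course
(induced competence output offset by ribosomal/tRNA shutdown, as in real
rRNA-depleted libraries); without this, FPKM — which is
composition-sensitive — would not track the induction that size-factor
normalization recovers.  Regulon rules: Δcrp silences CRP-S and CRP-N
induction, Δsxy silences CRP-S only.

Libraries sample fragments mass-proportionally from the pooled molecules
of `n_cells` cell-equivalents (default 50 per rate unit, so that
replicate-to-replicate variation reflects fragment sampling rather than
per-molecule Poisson noise; all calibrated ratios are invariant to this
scale).  Insert sizes are lognormal with batch-specific parameters
(batch1: median 250 nt, σ_log 0.25; batch2: median 300 nt, σ_log 0.22),
conditioned ≥ the 100-nt read length by resampling and truncated to the
molecule length.  Reads are emitted as a FASTQ pair (R1 on the transcript
strand, R2 reverse-complement, all qualities 'I'; sequencing error is off
by default — none of the analyses depend on error modeling) plus a truth
SAM with exact POS/TLEN/FLAG on the strain-specific composite reference
(locus followed by spacer-separated background genes).  Identical seeds
reproduce outputs byte for byte.

Cleavage, the simulated analogue of nonspecific toxin ribonuclease
activity, cuts each molecule at Poisson(rate × length/1000) uniform
points before fragmentation and discards pieces shorter than the 130-nt
size-selection floor.  Packaged rates are nonzero only where toxin is
expressible and antitoxin absent (ΔtoxA): 0, 0.5, 1.0, 2.0 cuts/kb at
t = 0, 10, 30, 100 — toxin accumulates after induction, so the
insert-size difference grows with time from ~0.

What the simulator does **not** emulate: rRNA depletion artifacts, GC and
positional bias, duplicate reads, sequencing error (switchable), genome
content beyond the anchored window plus the background set, and
population heterogeneity in competence (real cultures induce in no more
than about half of cells; an `n_cells` mixture could represent this but no
default asserts it).  Passing tests therefore demonstrate method
correctness under idealized library statistics, not robustness to every
real-data artifact.

## Quantification

Fragments (proper pairs, counted once via the mate with positive TLEN)
are assigned to the gene containing the fragment midpoint (pos +
TLEN//2) — unambiguous in operon-dense genomes and exactly recoverable
against simulator truth.  Counting is unstranded (library strandedness is
not assumed).  Size factors are DESeq2's median-of-ratios:
exp(median over all-positive genes of log(count) − log(geometric mean)).
FPKM divides by *annotated wildtype* gene length; partially deleted genes
in mutant strains are therefore deliberate underestimates.  Fold-change
tables use log2 of replicate-mean normalized counts with a pseudocount of
1 to keep zero baselines finite.  Operon levels average member-gene FPKM
over genes *physically present* in the strain (a gene excised by the
construct is not a biological zero), and ratios vs wildtype at the
matched timepoint propagate SE by the delta method.

## Internal-promoter detection

Coverage is fragment-level (each position spanned by a template gets one
count), and fragment 5′-start counts are kept separately: a promoter is a
step in where fragments *begin*, which is sharper than a step in
coverage.  The detector fits a two-segment piecewise-constant Poisson
model to the start profile over a window (default −50 to +200 around the
toxin start, ≥ 100 starts required), takes the maximum-likelihood change
point by exhaustive scan (cumulative sums, O(n)), and computes the
likelihood ratio against the single-rate model.  Significance is a
parametric bootstrap: B = 200 single-rate Poisson profiles (a
runtime/resolution compromise; p ≥ 1/201 ≈ 0.005), one-sided call rule
requires downstream rate > upstream rate and p < 0.01.  Measured error
rates under the packaged conditions: false positives 0-2/500 on null
profiles; localization of the ΔtoxA P2 within ±5 nt (in practice exactly
+30) in ≥ 95% of runs with ≥ 2000 operon fragments.

Position contrasts report normalized coverage (mean ± SE over replicates)
at offsets 0 and +100 from the toxin start codon, in wildtype coordinates
lifted onto each strain's own reference (positions deleted in a strain
are NA, e.g. +100 in ΔtoxT).  The +0/+100 convention follows the
coverage-figure anchoring of the study's main text (position 0 = toxT
start codon); the figure caption's alternative anchoring (toxA start) is
a known internal inconsistency of the source and is not adopted.

## Insert-size shift test

|TLEN| histograms (leftmost mates; values > 2000 nt discarded as
structural artifacts, counted) are compared only within a library batch —
independent preparations differ in size selection, so cross-batch
comparisons are refused, not down-weighted.  The statistic is the
rank-sum Z of the first library; the null is a label permutation over the
pooled inserts (seeded; libraries subsampled to 20k inserts to bound
cost), one-sided for "shorter in the first library".  The figure-style
summary is the quantile-wise difference (1st-99th percentiles).  The
time-course report adds a Spearman trend of median difference against
time per batch.  Null p-values are uniform (KS test over 200 seeded
runs), and the permutation p matches the exact Mann-Whitney p on small
samples within Monte-Carlo error.

The k-mer depletion scan is a deliberately simplified stand-in for
assembly-based differential k-mer analysis: canonical k-mer counts per
million (k ∈ [8, 16], default 10), flagging k-mers at log2 ratio ≤ −1
with reference count ≥ a minimum.  It has no dispersion model, so it is
only meaningful at depths where a 2-fold change cannot be sampling noise;
the packaged tests use ≥ 150 reference counts.  With sequence-nonspecific
cleavage it finds nothing (the expected negative result); a planted
k-mer whose carrier fragments are removed is detected.

## Numerical and degenerate-input choices

* Saturated NG86 proportions (p ≥ 3/4) return infinity with a warning; ω
  is undefined (None/NA) when dS = 0.
* Codon alignment is a star alignment on the first sequence (BLOSUM62,
  open −11, extend −1, gaps back-threaded onto whole codons); exact for
  the indel-free cohorts the pipeline simulates, approximate for complex
  multi-indel inputs.  Internal stop codons are errors naming sequence
  and codon index; the start-codon check can be disabled for diverged
  cohorts whose start may legitimately have mutated.
* Fragments extending past a reference end are clipped and counted;
  insert draws below the read length are resampled (bounded at 100
  rounds, then clamped).
* The change-point scan handles zero-count segments by the 0·log 0 = 0
  convention.
* Cohort scans of unscannable genomes (no anchor, no recognizable toxA)
  are excluded from class counts and reported with a reason.

## Problem sizes

Packaged tests and the reproduction script run at desk scale: cohorts of
181-200 genomes, libraries of 25k-50k read pairs with 3 replicates,
100-500 repetitions for power/false-positive estimates, permutation
depths of 199-20 000.  These sizes were chosen so every estimate's
Monte-Carlo error is several times smaller than the tolerance it is
checked against.
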