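# Methods

This note documents the models and procedures implemented in `pforge`,
the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Coordinates and formats

All user-facing positions are signed integers anchored at the start codon:
−1 is the base immediately upstream of the ATG, so a 400-nt promoter spans
−400..−1. Internally sequences are 0-based half-open. Sequences travel as
FASTA (lower-case folded, non-ACGT rejected), motifs as MEME minimal
format (rows renormalized to sum 1, deviations logged), tables as TSV with
a mandatory header.

## PSSM scoring

A motif is a matrix of per-position base probabilities. The window score
is log-odds base 2 against a uniform background with a pseudo-probability
ε = 10⁻³ on both numerator and background:
score = Σᵢ log₂((fᵢ,ₛᵢ+ε)/(0.25+ε)). The published procedure never states
its scoring form; log-odds was chosen because every downstream step
(permutation p-values, argmax positions, greedy refinement) is rank-based,
so any monotone transform of the true form gives identical decisions.
Scanning is forward-strand only: the target is a promoter in a fixed
orientation.

## Empirical p-values

Every significance call is a permutation test:
p = #(real ≤ random)/N with N = 100 by default, ties counted against
significance exactly as the definition reads. Note the attainable null
rate at α = 0.05 is 6/101 ≈ 0.059 for exchangeable continuous statistics;
the calibration tests allow for this discreteness. Position scans compare
the observed score at each position with the score *at the same position*
in shuffled promoters (the procedure computes scores at all positions of
each permuted promoter and a p-value per position; a promoter-wide-max
null would be the alternative reading). Shuffles are uniform
mononucleotide permutations, which preserve base composition and hence GC
exactly; dinucleotide structure is not preserved.

## Motif discovery

The published pipeline names only "a differential enrichment algorithm".
Implemented: a seed-based scheme in the DREME family.

- Every k-mer (k = 6..10) present in the target set is screened by a
  one-sided hypergeometric test on per-sequence presence, target versus
  reference. When the reference contains the target (over vs all), the
  reference alone is the sampling population; otherwise the union is.
- The 25 best seeds per k are re-tested counting presence with at most one
  mismatch for k ≥ 7 (at k = 6 a one-mismatch neighborhood saturates a
  few-hundred-nt promoter, so presence is exact there). The final p-value
  is Bonferroni-corrected over every k-mer present in the target set
  across all k.
- Significant seeds, most enriched first (ties prefer the shorter,
  more parsimonious seed), are assembled into PSSMs from their best
  (≤1 mismatch) occurrence per target sequence, with pseudocount 0.1;
  uninformative edge columns (< 0.25 bits) are trimmed. A seed that
  aligns to an already-accepted seed with at most one mismatch in a
  near-full overlap is absorbed.

The two-stage screen re-uses the exact-presence statistic to rank seeds
before the mismatch-tolerant test; this is a compute-saving heuristic and
mildly optimistic for seeds near the significance boundary. Motif counts
are data-dependent outputs, not contracts. Discovery runs in four
target/reference configurations per dataset (over vs all, over vs under,
under vs all, under vs over), direction-tagged by the target group.

## Motif similarity

Columns are compared by s = (Exp − Obs)/Exp, Obs = Σⱼ −(f₁ⱼ−f₂ⱼ)²,
Exp = ΣⱼΣₖ −(f₁ⱼ−f₂ₖ)²/4. The expected term as printed in the source
(inner term without the second index) equals the observed term and makes
every score zero; the cross-index reading implemented here is the only
non-degenerate one. Exp = 0 exactly when both columns are uniform; that
case scores 1 by continuity with the identical-column limit. For two
motifs of lengths L₁, L₂ every relative offset with at least one
overlapping column (L₁+L₂−1 configurations) is evaluated after padding
both matrices with uniform 0.25 columns to the union span; the score is
the mean column score over the union span and the similarity the maximum
over offsets. Averaging over the union span (rather than the shorter
motif) means overhanging informative columns dilute the score — a
sub-motif of length k inside a length-L motif scores about k/L, not 1.
Match significance permutes the nucleotide rows of the partner motif,
which preserves per-column mass but scrambles base identity.

## Site selection and the insertion rule

Significant positions are pooled across the relevant promoter group;
xᵢ counts promoters with a hit starting at coordinate i. A candidate
window sits at every observed significant coordinate (not every integer),
spans ±4 nt, and scores Xⱼ = Σᵢ xᵢ over its span with prevalence
percent = Xⱼ/Σxᵢ·100 (denominator = all hit occurrences). The maximal
window is kept (ties toward the smallest |center|). Motifs from the
variant library survive a strict >6.5% prevalence cut; endogenous-set
motifs survive if their matched library motif's window center lies within
±20 nt, and their consensus position is the midpoint rounded toward the
endogenous center. The insertion decision compares
max(score over candidate positions in the target promoter) with
max over positions of the mean score across source promoters covering
that position (strict inequalities; equality fails both directions).
The insertion coordinate is the position with the best across-promoter
mean (for insertions) or the target's own strongest site (for removals).

## Greedy refinement

From the fragment at the chosen site, each iteration enumerates all
single-base substitutions at positions that are neither masked nor the
position changed in the immediately preceding iteration, applies the
strictly best one, and stops when none improves. Freezing is read as
one-iteration-only (not cumulative); strict improvement guarantees
termination in ≤ 3L substitutions either way, and for an additive
per-column score the optimum is the per-column argmax/argmin, verified
exhaustively in tests. Ties among substitutions break by smaller
coordinate then alphabetical base. "Insertion" is substitution-in-place:
promoter length is preserved, matching a fixed-length cloning slot
between KpnI (GGTACC) and SwaI (ATTTAAAT), whose spans are masked by
default.

## Feature extraction

- *Folding*: minimum-free-energy secondary structure (ViennaRNA
  nearest-neighbor model applied to the sequence) in 40-nt windows at
  step 1 (window indexed by its first base), plus the window average and
  the whole-sequence value. The published analysis used an RNA-folding
  routine on promoter DNA; the same convention is kept.
- *Mutations*: per-position indicators against the control plus the count.
- *ChimeraARS*: mean over start positions of the longest substring present
  anywhere in a reference promoter set (0 when none).
- *Motif scores*: max sliding log-odds per motif (inserted, discovered,
  external catalogs).
- *Promoter strength*: a 4×41 energy matrix in k_BT over coordinates
  −41..−1 relative to the TSS; per-position contributions, their sum and
  mean. The published source matrix is not reprinted anywhere accessible,
  so the matrix is an input; a documented synthetic stand-in
  (`toy_energy_matrix`) ships for tests and examples.
- *Composition*: mono-/dinucleotide counts and frequencies plus GC.
- *RBS*: duplex free energy of every 6-nt window (as RNA) against the
  anti-Shine-Dalgarno core (default ACCUCCUUA, configurable), computed
  with the nearest-neighbor duplex model.

Reduction: folding windows with |Spearman ρ| > 0.99 collapse greedily
along increasing position to the first representative (constant columns
kept and flagged); mutation indicators at adjacent (±1 nt) coordinates are
averaged — the source states "similar positions" without a radius.

## Response modelling

Difference curves Δ(t) = lum₊ − lum₋ are linearly interpolated onto a
common grid with boundary values held constant outside the measured span.
Response variables: max Δ, mean Δ, max consecutive slope, time of first
maximum. K-means clustering uses correlation distance via row
standardization (squared Euclidean on z-scored rows ∝ 1 − r); K is chosen
by silhouette (correlation metric), with Davies–Bouldin reported and
silhouette winning disagreements.

Regression harnesses (per repeat, 10 repeats, fresh random split):
linear 60/20/20 with forward selection on test-set Pearson r; LassoCV
80/20 on standardized features; gradient-boosted trees 60/20/20 with
forward selection and hyperparameters from one budgeted random search
(50 trials, validation R², shared across repeats). Forward selection
searches only the top-40 features by training-set |r| with the target —
with hundreds of post-reduction features an unscreened greedy boosted-tree
search is minutes per repeat — and uses a small surrogate tree model
during the search, refitting the final model with the searched
hyperparameters. The accepted objective is non-decreasing across steps.

Classification: tertiles of control-relative max difference give three
balanced classes; RBF-kernel SVM and boosted trees, 80/20 per repeat with
forward selection on held-out accuracy. The permutation null refits each
classifier on 100 permuted-label draws using the features selected on the
real labels (re-running the selection search per permutation is
prohibitively slow and only makes the null easier to beat).

Importance: cross-repeat selection frequency (top 10% after merging
folding windows within 10 nt and motif features one substitution apart),
boosted-tree gain, and additive per-feature attributions (TreeSHAP as
implemented inside xgboost). Attribution additivity holds to float32
(xgboost's prediction dtype): ~10⁻⁷ on unit-scale targets, ~10⁻⁴ at raw
RLU magnitudes.

Per-variant significance: Welch's t-test of each variant's replicate
response values against the control's. With two replicates per group this
test is fragile — it matches the published design and is not endorsed
statistically. The FDR is the mean number of significant calls over
label-randomized datasets divided by the observed number.

EC200: the smallest dose at which the induced/uninduced ratio reaches 2,
interpolated linearly in log(dose)-log(ratio) between bracketing doses;
an exact hit returns the dose, a curve that never reaches 2 returns a
"not reached" sentinel (None), a non-monotone curve uses the first
crossing with a warning.

## TF scanning

Each TF matrix contributes its maximum sliding score and position; the
null compares maxima against composition-preserving promoter shuffles
(max-vs-max, since the statistic of interest is the best site). The
top-vs-bottom 20% comparison uses a two-sided Wilcoxon rank-sum test,
exact for group sizes ≤ 12 without ties.

## Synthetic data

The generators are pure functions of (parameters, seed) and return their
planted truth.

- *Endogenous set*: 500 iid promoters of 400 nt (uniform composition by
  default; an AT-rich E. coli-like option A=T=0.30 exists because motif
  recovery difficulty depends on background). 10% are responders whose
  inducer-condition expression shifts by 3 disparity-sd units; 80% of
  responders carry the planted 8-mer (per-base substitution rate 0.1,
  information content ≈ 11 bits) at −120, and 5% of the rest carry it
  with no effect. Noise is paired: the baseline varies per gene and is
  shared between conditions, so the stated effect is on the disparity
  scale.
- *Variant library*: 2 000 variants of one base promoter; non-carriers
  mutate 1–3 of 147 designated sites (per-site effects N(0, 0.15) on
  log₁₀ fluorescence), 10% carry the planted consensus at −120 and gain
  log₁₀(4) under the inducer — a fourfold response, the magnitude an
  engineered variant is expected to show. Reads are multinomial (depth
  200 per condition) over 16 log-spaced bins with a Gaussian sorting
  kernel (sd 0.15 log₁₀ units).
- *Luminescence*: Δ(t) = amplitude · logistic(t; onset 2.5 h, rate 1.5)
  plus noise, hourly over 10 h, two replicates; the amplitude is linear
  in designated standardized features. The onset reproduces the
  characteristic ~2.5 h induction lag.

What the generators do **not** emulate: real promoter phylogeny and
shared regulatory architecture (background is iid), RNA-seq count noise,
FACS gating artifacts beyond the multinomial kernel, plate effects and
replicate structure in luminescence, or any actual inducer biology.
Passing recovery tests therefore shows the procedures are correct and
calibrated under their own assumptions, not that they would recover
motifs from any particular organism's data.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
study scale (500 endogenous promoters, 2 000 library variants at depth
200) across seeded repetitions (20 seeds in the recovery test, 5 in the
acceptance script, which reports its n), and the modelling stage on an
80-variant panel of a 120-nt promoter with 10 cross-validation repeats
and 100 label permutations.

## Known limitations

- Forward-strand scanning only; no reverse-complement occurrences or
  gapped/EM-refined motifs.
- The discovery Bonferroni factor (k-mers present in the target) is
  conservative for strong motifs and anticonservative compared with 4^k
  when targets are few and short.
- The similarity metric is unstable for nearly-uniform columns (a ratio
  of two near-zero quantities); exact uniformity is special-cased, near
  uniformity legitimately scores near 0.
- Welch t-tests at n = 2 per group, as designed, have almost no power
  and unstable p-values; the randomization FDR is the more meaningful
  summary.
- The shipped energy matrix is synthetic; promoter-strength features are
  only as meaningful as the matrix supplied.
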