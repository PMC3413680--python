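# Methods

## Model and objective

The package treats an experiment collection as a genes × arrays matrix with
a partition of arrays into experiments; an experiment (one study's
time-points/conditions) is the atomic unit of selection. For a functional
category *C* and background *B* (genes annotated to other categories;
unannotated genes are excluded), and an experiment subset *S*, the profile
of a gene over *S* is the concatenation of its values on the member
experiments' arrays, in manifest order. Correlation over a subset is the
sample Pearson correlation of those concatenated profiles — not an average
of per-experiment correlations — because vector length is exactly the
quantity that trades significance against dilution.

The discrimination objective for *S* is the one-sided two-sample *t*-test
(pooled by default; Welch available) that mean(A) > mean(B), where A holds
the |C|(|C|−1)/2 within-category correlations (upper triangle) and B the
|C|·|B| category-background correlations. Background-background pairs carry
no information about *C* and are never computed. The test's i.i.d.-normal
assumptions are knowingly violated (correlations are bounded and share
genes); the p-value is used as a comparable score, not as calibrated error
probability. An optional Fisher transform (atanh of all correlations before
the test) is provided for users who want closer-to-Gaussian inputs; it is
off by default.

### Log-space p-values

With hundreds of A values and thousands of B values, t-statistics of 40–300
arise routinely and their tail probabilities underflow `float64` (the
smallest subnormal is ~5e-324, i.e. log p ≈ −745). Comparing such p-values
is the whole search, so the Student-t upper tail is evaluated directly in
log space through the regularized incomplete-beta continued fraction
(Lentz's algorithm with the standard symmetry switch at
x = (a+1)/(a+b+2)). Agreement with `scipy.stats.t.sf` is ~1e-9 relative
where scipy is finite, and ~1e-8 against arbitrary-precision evaluation
(mpmath) down to log p ≈ −20000.

## Search

1. **Seeds.** Every single experiment is scored by the objective; the best
   K are kept (default K = 25 — selection quality is quite insensitive to K
   over a wide range; the CLI clamps K to n).
2. **Growth.** Per seed, one randomized pass over all other experiments;
   each candidate is tentatively appended and the expanded list rescored.
3. **Acceptance rule.** Default `improve`: keep the candidate iff the
   expanded list's p-value is below L (default 0.05) *and* strictly better
   than the current list's. A pure `threshold` rule (keep iff p < L) is
   also provided, but as a default it degenerates: whenever the category
   signal is strong the A/B test stays significant even after heavy
   dilution — the pooled t grows with pair counts, and with ~600 A and
   ~7000 B values a mean difference of under 0.01 is already significant at
   0.05 — so the threshold rule accepts essentially every candidate and
   returns the whole collection. Requiring improvement keeps grown lists
   small and relevant while reducing to the same behaviour when the signal
   is marginal.
4. **Choice.** The trace with the lowest final log p wins; ties break
   toward fewer experiments, then lexicographic ids. The final log p always
   equals the objective recomputed on the returned set (asserted in tests).
   The t-test count is exactly n + K(n−1): quadratic, vs 2^n for exhaustive
   search (2^44 ≈ 1.76 × 10^13 for a 44-experiment collection).

RNG discipline: one master seed; each seed-list's candidate order comes
from an independent `SeedSequence` child indexed by list rank, so raising K
extends, rather than reshuffles, earlier lists. Cross-validation derives
fold shuffling and per-fold selection seeds the same way. All results are
bit-reproducible for a fixed master seed.

The objective uses **unfiltered** correlations: within one search the A/B
sample sizes should stay fixed, and the t-test itself normalizes for vector
length. Significance filtering (see below) matters when *comparing* value
distributions across subsets of different sizes, i.e. in evaluation and
visualization; `objective_alpha` exposes the filtered variant for
experimentation. A `background_sample` option caps the number of background
genes per run (deterministic subsample) for very large backgrounds; it has
no tuned default.

## Evaluation

Length-bias control: a correlation computed over fewer arrays is larger by
chance, so evaluation either filters values (histograms) or zeroes scores
(ROC tasks) that fail the two-sided t-transform test
`t = r·sqrt((n−2)/(1−r²))`, df = n−2, at α = 0.05 by default.

* **Histogram comparison** — within-category correlations for the selected
  subset vs the full collection, each filtered at its own vector length;
  one-sided pooled t-test on the absolute values (selected > all), in log
  space.
* **Pair classification** — positives: category-category pairs; negatives:
  category-background pairs; score = the pair correlation. AUC is the
  rank/Mann–Whitney probability with ties counted ½, identical to the
  trapezoidal area of the tie-grouped ROC curve (asserted against an
  exhaustive pair-enumeration oracle in tests).
* **GBA prediction** — a gene's score is the sum of its correlations to the
  training category genes; undefined correlations contribute zero.
* **Cross-validation** — genes are split into 10 folds, stratified so
  category genes appear in every fold (an unstratified split can leave a
  fold with no positives for a 25–40 gene category; this is a deliberate
  deviation from a plain random split). Per fold, selection sees only the
  training genes; evaluation pairs have at least one endpoint in the
  held-out fold (pairs wholly inside a small fold are too few for a stable
  ROC — this convention is recorded in the report metadata). ROC curves are
  vertically averaged on a 101-point FPR grid. The fold-level comparison is
  a *paired* one-sided t-test on the ten (1−AUC) values — both numbers in a
  pair come from the same fold; identical folds give p = 0.5 by convention.
* **Specificity sweep** — pair-mode cross-validation at each level of a
  user-supplied leaf-to-root chain of nested categories, reporting
  mean(1−AUC)_all − mean(1−AUC)_selected per level. Ontology traversal is
  out of scope; callers flatten the hierarchy themselves.

## Missing data and degenerate inputs

Missing values stay masked (`NA` on disk, NaN in memory); correlations use
pairwise-complete positions. A pair with fewer than 3 complete positions or
zero variance is *dropped* (counted, never imputed); dropped pairs are
excluded from both the objective and evaluation. A subset whose every pair
is undefined is an error. Degenerate t-tests (zero pooled variance) return
log(0.5) at equal means, ±∞ otherwise. Ten-thousand-replicate checks
confirm the t-transform p-value is KS-uniform under the bivariate-normal
null.

## Synthetic data

`SyntheticSpec` defaults define the standard planted study: 40 category
genes, 200 background genes in 20 blocks of 10, 4 relevant + 16 irrelevant
experiments of 6 arrays, signal_sd/noise_sd = 2. Category genes in a
relevant experiment share a per-array latent `N(0, signal_sd²)` plus
i.i.d. `N(0, noise_sd²)` noise; elsewhere they are pure noise. Each
background block shares its own latent in *every* experiment, so
category-background pairs are uncorrelated but the background has realistic
co-expression structure. Values are rescaled so each gene's marginal
variance is `noise_sd²` in every experiment — the generator emulates
*normalized* expression data. This matters: without the rescale, relevant
experiments carry (signal_sd² + noise_sd²)/noise_sd² times more variance,
concatenated irrelevant arrays barely dilute the correlation, and the
dilution phenomenon the generator exists to reproduce disappears. Under the
scaled model the expected within-category correlation in a relevant
experiment is signal_sd²/(signal_sd² + noise_sd²) = 0.8 at the default
ratio, and mean |r| decays toward the null level
E|r| ≈ √(2/(π(n−1))) as irrelevant experiments are appended
(`dilution_curve` reproduces both regimes; the null curve matches the
closed form within 15% at 50-replicate averaging).

What the generator does **not** emulate: probe-level artifacts, platform
normalization quirks, heavy-tailed noise, anti-correlated (repressed)
signal, overlapping categories, or cross-talk genes (an optional
`shared_gene` flag plants a single two-block gene for qualitative
exploration only). Passing tests therefore demonstrate correctness of the
machinery and recoverability of a clean planted signal, not performance on
real microarray collections.

## Problem sizes used in tests and the acceptance script

Stochastic claims use 20 master seeds each: planted recovery and
cross-validated improvement run on the default planted collection
(240 genes × 120 arrays, K = 10); the greedy-vs-exhaustive comparison uses
a 10-experiment version (20/100 genes, 2 relevant, K = 5) so all 1023
subsets can be scored; dilution curves use a 1-relevant + 6-irrelevant,
12-category-gene design averaged over 50 replicates per seed; the
specificity sweep uses a 4-level chain built by absorbing one background
block per level. These sizes keep a full run to a few minutes on one CPU
while leaving all pass margins wide.

## Known limitations

* The greedy search carries no optimality guarantee; it is a heuristic that
  empirically lands in the best decile of the exhaustive objective
  distribution on 10-experiment problems.
* Objective p-values are scores, not calibrated probabilities (dependent,
  bounded samples).
* On strongly planted synthetic data the GBA classifier saturates: summing
  ~36 training-gene correlations averages noise away, so both the selected
  subset and the full collection reach AUC ≈ 1.0 and the cross-validated
  *improvement* is measurable only in pair mode. Weaker or sparser signal —
  the realistic regime — is where GBA-mode gains appear.
* Selection treats the manifest as ground truth (e.g. organ-split studies
  must be split upstream) and consumes already-flattened gene sets; no
  ontology processing is performed.
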