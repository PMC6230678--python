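# Methods

This note documents the models, numerical choices, and limitations of
`fiscope`. It describes what the code computes; every number quoted here is
produced by the test suite or `scripts/acceptance.py`.

## Normalization model

A lane's measured count for probe *g* is treated as
`signal_g · lane_scale + background`, where `lane_scale` is a single
multiplicative technical factor per lane and `background` is additive
nonspecific binding. The pipeline removes these in three stages, in the
order background → positive-control scaling → housekeeping scaling
(platform-conventional):

1. **Background**: subtract the mean of the lane's negative-control counts
   (default) or mean + 2·SD (sample SD, ddof = 1) from endogenous and
   housekeeping probes, flooring at zero. Matrix-only inputs without
   negative probes may set the method to `none`.
2. **Positive scaling**: multiply each lane by
   `grand_geomean / lane_geomean` of the positive spike-in counts, where
   the grand geometric mean is taken over the per-lane geometric means.
   This equalizes spike-in response across lanes.
3. **Housekeeping scaling**: the same construction on the 5 housekeeping
   genes, applied after positive scaling. After this stage the
   housekeeping geometric mean is identical across lanes by construction
   (tested at 1e-9 relative).

Zeros inside a control geometric mean would make it collapse to zero; when
any zero is present among a lane's control probes, 0.5 is added to that
lane's control counts only. This keeps the geometric mean defined while
perturbing typical control counts (tens to thousands of counts) by well
under a percent. Lanes with a scale factor outside [0.3, 3] are flagged
`scale_factor_out_of_range` but not dropped; lanes whose housekeeping
signal is entirely zero are excluded with a warning, since no content
scaling is possible for them.

The construction makes normalization invariant to a global rescaling of
all counts and idempotent (re-estimating factors on already-normalized
data multiplies every lane by the same constant 1).

## Differential expression

Each gene is tested with the tie-corrected Kruskal-Wallis statistic across
the three groups (chi-square reference with k−1 df), followed by Dunn's
post-hoc z for each pair,

    z_ij = (R̄_i − R̄_j) / sqrt([N(N+1)/12 − Σ(t³−t)/(12(N−1))](1/n_i + 1/n_j)),

with midranks for ties and two-sided normal p-values, Bonferroni-adjusted
over the three pairs (Holm available). When every observation is identical
the statistics degenerate; H is defined as 0 with p = 1.

Rank tests run on `log2(normalized + 1)` — the monotone transform leaves
them unchanged but is the scale used by the scoring stage. Fold
differences are `log2((median_A + 1)/(median_B + 1))` on the raw
normalized scale; the pseudocount of 1 keeps the ratio defined at zero
medians and is negligible against typical normalized values.

The "adjusted significance" that feeds the transcript weights is a
Benjamini-Hochberg q computed across the endogenous genes on the
*unadjusted* Dunn p of the impaction contrast (one point per transcript,
as in a volcano plot); a config switch substitutes the Dunn-adjusted p.
The chi-square approximation is used at all group sizes — the cohorts this
targets have ≥13 per group; the exhaustive permutation distribution
appears only as a test oracle, where the comparison uses mid-p values to
account for the discreteness of the exact law at N = 8.

## FI-score

The composite score is a one-factor projection with fixed loadings, not an
iterative factor-analysis fit — with a few dozen patients a 74-gene
loading matrix cannot be estimated, and the loadings are derived externally
from the DE results:

* weight: `w_g = log2FD_g · (−log10 q_g)` if `q_g < α` (default α = 0.05),
  else 0; weights L1-normalized so Σ|w| = 1, signs preserved. This is the
  simplest monotone combination of the two volcano axes; a rank-based
  variant is available by option. If no gene passes the gate the package
  raises an "empty signature" error rather than inventing a score.
  q-values are floored at 1e-300 before the log so numerically zero q
  cannot produce infinite weights.
* raw score: `s_p = Σ_g w_g · z_{g,p}` where `z` standardizes
  `log2(normalized + 1)` per gene across the scored cohort (sample SD,
  ddof = 1; zero-spread genes contribute 0). Only EoE patients are scored;
  controls never enter the cohort statistics or receive calls.
* standardized score: `(s − mean)/SD` over the scored cohort (ddof = 1);
  degenerate (zero-SD) score vectors are an error.
* call: FI-positive iff standardized score ≥ cutoff (boundary inclusive).

Weights are computed in-sample on the same cohort that is scored, matching
how a retrospective signature is derived; `loo_scores` provides an
explicitly separate leave-one-out mode in which weights, cohort means and
SDs are re-derived with each patient held out (expected to perform no
better than in-sample, and tested for that direction).

## ROC and cutoff

AUC is the Mann-Whitney probability (ties get half credit), identical to
the trapezoidal area under the empirical ROC (tested to 1e-12). Its
standard error uses the Hanley-McNeil closed form with
Q1 = A/(2−A), Q2 = 2A²/(1+A); DeLong is deliberately not implemented — the
closed form is the convention this analysis reports. Candidate cutoffs are
midpoints between adjacent distinct scores plus sentinels beyond the
extremes; `youden` maximizes sensitivity + specificity − 1 (ties broken
toward the lower threshold, favoring sensitivity), `max-specificity`
maximizes sensitivity among cutoffs with specificity exactly 1 and falls
back to a threshold above the largest negative score. Confusion-matrix
ratios with empty denominators are reported as missing, never as 0.

## Cohort statistics

Two-sided Fisher exact p-values use the probability-mass definition (sum of
the hypergeometric mass of every table, at fixed margins, no more probable
than the observed one); a zero margin admits a single table and returns
p = 1. The implementation delegates to scipy's log-factorial evaluation
and is tested against an exact rational enumeration oracle at 1e-10.
Display percentages are rounded half-up; full precision is retained in the
tidy frames. Denominators exclude missing values per trait, so a trait
tested in only part of a group is summarized over the tested subset.

## Diagnostic loops

The EoE gate is `p(EoE) > 25` (strict) on a 0–100 probability triple
summing to 100; the IGHE loop flags `score > 37.5` (strict). Both loops
are pure functions of their score and annotate patients independently — no
ordering between secondary loops is imposed. The probability model behind
p(EoE) is deliberately a pluggable stand-in: a regularized multinomial
logistic model (C = 1) on per-gene standardized log2 expression,
serializable to JSON, with a stratified out-of-fold mode so no patient is
gated by a model that saw it in training. The FI loop runs only on samples
passing the gate (or on labeled EoE samples when the gate is disabled).

## Synthetic cohort generator

The generator defines the conditions all property tests run under:

* groups of 18 controls / 13 EoE without impaction / 14 with impaction;
* 74 endogenous genes (the eight named transcripts plus stable
  placeholders), 5 housekeeping genes, 6 positive spike-ins on a 4-fold
  ladder (128 → 0.125 fM, 150 counts/fM response), 8 negative controls;
* per-gene baselines log-uniform on [50, 5000], drawn once per panel seed,
  so abundances are heterogeneous;
* endogenous and housekeeping counts negative binomial (size = 10, i.e.
  ~32% biological CV) around `baseline · group fold · lane scale`, plus
  Poisson(10) background; positives Poisson around
  `concentration · response · lane scale`; negatives Poisson(10);
* a log-normal per-lane scale (sd 0.2 by default) applied to endogenous,
  housekeeping and positive probes alike — exactly the effect
  control-based normalization can remove by construction;
* planted effects: EoE-wide up-regulation (e.g. *CCL26* ×12) shared by
  both EoE groups, and impaction-specific down-folds in [0.3, 0.5] on
  *CPA3, FCER1B, CCL2, IL4, IL5, NOS2, HIF1A*. For the mast-cell/Th2
  genes the EoE up-fold roughly inverts the impaction down-fold, so
  impaction patients return toward control levels — the pattern the
  impaction subgroup is characterized by, and a necessary property for
  pooled-rank post-hoc tests to be able to flag these genes at all (a
  group strictly sandwiched between the other two has a bounded Dunn z).
  The motility genes' down-folds (0.4, 0.45) are graded to the strong
  per-transcript significance this contrast shows in practice.
* clinical metadata: independent Bernoulli symptom draws at per-group
  prevalences shaped like a pediatric EoE cohort (dysphagia universal in
  the impaction group), zero tissue eosinophilia in controls.

What the generator does **not** emulate: correlation between genes (counts
are independent given the lane), age/covariate structure, cartridge
batches, longitudinal visits, histology, or any coupling between symptoms
and expression. Passing tests therefore demonstrate that the statistical
machinery recovers planted effects of realistic size under realistic count
noise — not that the specific published operating point (AUC 0.99, cutoff
0.03) is reproduced, which would require the undeposited patient data.

## Problem sizes and determinism

All stochastic tests fix their seeds. The recovery acceptance property
uses 50 simulated cohorts at the study's group sizes; null calibration
uses 2,000 replicate null genes and 50 label permutations; the exact
Fisher oracle is exhausted on a grid up to 8 per cell and sampled up to
table totals of 60. Seeds derived from user seeds stay below 2^31.

## Known limitations

* The exact functional form of the published "weighted factor analysis"
  and its adjusted-significance family are not public; both are config
  options here, and the printed cutoff (0.03) and operating point are not
  expected to reproduce exactly without the original cohort.
* The default probability model is plumbing around the gate logic; it does
  not replicate any published model's coefficients.
* In-sample AUC on a 27-patient cohort with in-sample-derived weights is
  optimistically biased; the leave-one-out mode exists precisely to
  quantify that bias.
* Two ambiguities in the source material are carried as-is: the chemokine
  panels include both *CCL2* and *CCL26* (both on the default panel, no
  disambiguation attempted), and *FCERIB*/*FCER1B* are treated as the same
  probe, named *FCER1B*.
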