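# Methods

This note documents the models, estimators and numerical choices behind
`synscreen`, and what the synthetic study designs do and do not show
about real screening data.

## Viability normalization

Raw well signals are normalized per plate group:

    v = (signal − mean(neg_control)) / (mean(pos_control) − mean(neg_control))

so the DMSO-treated mean maps to exactly 100% viability and the empty-well
(or kill-control) mean to 0%. The transformation is affine-invariant —
adding a constant to, or rescaling, all signals on a plate leaves
viabilities unchanged — which is why the simulator's background offset
(below) is invisible downstream. Normalized viabilities are *not*
clipped: values above 1 are genuine noise above the DMSO mean and carry
information for least-squares fitting. Clipping to [0, 1] happens only
where a formula requires a probability (Bliss, AUC integrand).
Replicates are averaged at the viability-point level before fitting,
with the per-point SEM retained. Normalization is per plate group (one
cell line per plate in the simulated designs); whether a screen should
share control means across plates is a data-preparation decision the
caller makes by choosing the grouping keys.

## Dose-response model

Viability follows the four-parameter logistic

    V(c) = einf + (e0 − einf) / (1 + (c / ec50)^h)

with baseline `e0` (≈1 for viable untreated cells), plateau `einf`,
inflection `ec50` (nM) and Hill slope `h > 0` for decreasing curves.

Two metrics are derived per curve:

* **Absolute IC50** — the smallest tested concentration where the fitted
  curve crosses 50% of untreated control, by closed-form inversion of
  the 4PL. This is deliberately *not* the EC50 inflection: a compound
  plateauing at 60% viability has an EC50 but no IC50. Curves that
  never reach 0.5 inside the tested range are censored as `>cmax`
  (resp. `<cmin` when already below 0.5 at the lowest dose); censored
  values enter downstream fold changes as the censoring bound, which is
  the conservative substitution (it understates improvements).
* **AUC** — the mean of `clip(V, 0, 1)` over log10 dose on the tested
  range, by 257-point trapezoid quadrature. AUC ∈ [0, 1], 1 for a flat
  resistant curve; lower = more sensitive. This is the convention used
  by large panel resources whose AUC matrices the enrichment analyses
  consume; one convention is used throughout.

### Fitting

Fitting is bounded nonlinear least squares in
(log10 ec50, h, e0, einf) with box constraints e0 ∈ [0.5, 1.5],
einf ∈ [−0.1, 1.2], h ∈ [0.1, 10], log10 ec50 within ±2 decades of the
tested range — bounds that keep 6-point fits identifiable. A fixed 5×3
multi-start grid over (log10 ec50, h) makes the procedure deterministic
(no RNG); all 15 starts are iterated together by a batched,
bounds-projected Levenberg–Marquardt with analytic Jacobian (one 4×4
solve per start per iteration), and the selected best-SSE candidate is
then refined by a scipy trust-region pass. The batched stage exists
because a screen fits hundreds of tiny 6-point problems and
general-purpose solver overhead, not arithmetic, dominates at that
size; a test cross-checks that the multi-start result matches or beats
a single scipy trust-region run. SSE ties (within a relative hair) are
broken by smaller h, then smaller ec50.

Degenerate inputs: a flat response leaves the slope unidentifiable and
is flagged `converged=False`; non-converged fits fall back to
model-free metrics (IC50 by log-linear interpolation between observed
points bracketing 0.5, AUC by trapezoid on the observed clipped
points).

**Sensitivity classification.** A line is *insensitive* to a compound
when its measured viability stays strictly above 50% at the configured
top dose (default 10 µM); exactly 50% counts as sensitive. The
classification is undefined off that dose and raises instead of
guessing.

**AUC Z-scores** are per-compound across all cell lines, sample sd
(n−1); constant columns yield zeros with a warning.

## Combination synergy

Effects are inhibition fractions `f = clip(1 − v, 0, 1)` — Bliss
independence multiplies survival probabilities, so its inputs must be
probabilities. The expected combined inhibition is
`E = fa + fb − fa·fb`, and the per-cell excess is
`observed − E(measured margins)`; positive excess = synergy. Cells with
a missing monotherapy margin are undefined and excluded from averages;
the averaging domain is all cells with both doses positive (margins
carry zero excess by definition and would dilute the score).

Anchored screens score each (cell line, anchor, library compound) with
three metrics, each averaged over the anchor concentrations — the
anchor drug's IC15/IC25/IC50 per cell line, obtained by inverting its
monotherapy 4PL at viabilities 0.85/0.75/0.50:

* `ΔEmax` = Emax(combination)/Emax(monotherapy) at the top library dose;
* `ΔIC50` = IC50(monotherapy)/IC50(combination), so > 1 means the
  combination improves potency;
* average Bliss excess.

Fold changes from a null baseline (monotherapy Emax 0, or a censored
monotherapy IC50 against a finite combination IC50 through the bound
substitution) are an explicit +∞ marker that satisfies any finite
threshold and propagates through the anchor average; 0/0 is 1.0.

A combination is a **hit** when ΔEmax > 5 or ΔIC50 > 5 or average
Bliss > 0, all strict. The Bliss threshold is exactly zero with no
noise floor — scored as printed — and the null behavior that implies is
quantified below. **Maximum effective synergy** is the largest excess
among cells whose observed combination viability is below 50%, i.e.
synergy that coincides with meaningful killing. **Cross-entity
overlap** intersects hit flags across cell lines, with compounds not
screened in a line excluded from that line's domain rather than counted
as misses.

Combination curves for ΔIC50/ΔEmax are normalized to untreated control
by default; an anchor-normalized mode (divide the combination series by
the anchor-alone viability) is available via configuration. Note the
default mode lets the anchor's own effect enter the combination Emax,
which inflates ΔEmax for weak library compounds; the anchor-normalized
mode measures only the effect beyond the anchor. Bliss excess always
uses the untreated-control scale.

## Differential sensitivity and enrichment

**Moderated t.** Each feature (compound AUC profile or gene expression
profile across cell lines) is fit by OLS against a shared design
matrix; residual variances are shrunk by empirical Bayes under
s² ~ s0²·F(d, d0). The prior (d0, s0²) is estimated by method of
moments on log s² — the estimator agrees with the Bioconductor
reference implementation to 1e-6 on shared fixtures (see the test
suite) — and the moderated t uses s̃² = (d0·s0² + d·s²)/(d0 + d) with
d + d0 degrees of freedom. A single feature, or d0 = 0, reduces exactly
to the ordinary t. One consequence worth knowing: the log-scale moment
estimator's finite-df correction means that even when all residual
variances are identical, s0² differs from s² by the factor
exp(log(d/2) − ψ(d/2)), so moderated and ordinary t then differ by a
common proportionality constant — orderings and rankings are unchanged.
Features with missing values need ≥ 3 observations per group (binary
designs) or ≥ p + 3 overall (continuous designs); the dropped count is
logged.

Designs: the pediatric-vs-adult contrast is intercept + pediatric
indicator on AUC (no further covariates by default); the biomarker
design is intercept + compound AUC (continuous) + tumor-type dummies on
expression, testing the AUC coefficient. Sign conventions: negative
NES in the compound-set analysis means the set's compounds are more
potent (lower AUC) in pediatric lines; negative t in the biomarker
analysis means higher expression accompanies lower AUC (greater
sensitivity).

**Enrichment.** Features are ranked by moderated t, descending, ties
broken lexicographically for determinism; non-finite t is dropped with
a warning. The weighted Kolmogorov–Smirnov running sum increments by
|t|^p/Σ_set|t|^p at member positions (p = 1 by default, the classic
weighting) and decrements by 1/(N − |set|) elsewhere; ES is the signed
extremum and the leading edge is the member prefix (suffix, for
negative ES) up to it. Significance uses member-label permutations:
`n_perm` random same-size sets from the ranked universe form the null;
NES = ES / mean(|null ES| of matching sign);
p = (1 + #{same-sign null at least as extreme}) / (1 + #{same-sign null}),
so the smallest attainable p is ≈ 2/n_perm — choose
n_perm ≫ n_sets/α when BH-adjusted calls are needed. Sets with fewer
than `min_size` (default 5) members present in the ranking are
skipped. Benjamini–Hochberg adjusts across the sets of one analysis.
Null scores are computed vectorized from sorted hit positions; an
independent pure-Python running-sum oracle pins the implementation in
the tests.

**Mutation association** is a convenience view: per-group AUC summaries
plus a two-sided Wilcoxon rank-sum p (exact where sample sizes allow).
The per-target volcano summary averages compound-level moderated t
within a target and carries the minimum adjusted p — a presentation
convenience, not an inferential procedure, and labelled as such in its
docstring.

## Synthetic study designs

The generators produce every input the pipeline consumes, with ground
truth serialized as JSON alongside.

* **Noise model:** additive Gaussian on the viability fraction,
  σ = 0.05 (a typical MTT-assay CV), independent per replicate well;
  2 replicates by default, averaged before analysis.
* **Signals:** scale 10,000 with a constant background offset of
  0.2·scale on every well so that empty wells remain non-negative under
  Gaussian noise; affine-invariant normalization removes it exactly.
* **Monotherapy:** 6-dose decade grid 0.1 nM–10 µM; truths e0 = 1,
  einf ~ U(0, 0.3), log10 ec50 ~ U(0.5, 3.5) (crossing 0.5 inside the
  grid), h ~ U(0.8, 2.5).
* **Combination matrices:** 10 doses in five-fold steps from 0.03 nM
  (the stated 10 µM endpoint is inconsistent with five-fold spacing
  from 0.03 nM; the spacing is kept and the top dose lands at 58.6 µM).
  Observed combination inhibition is clip(E_bliss + δ + ε, 0, 1) with a
  uniform planted excess δ. Default margin truths are partial-efficacy
  curves (einf = 0.4): where the independence expectation saturates
  near 1, clipping leaves no headroom to observe planted excess, so
  full-kill defaults would make recovery experiments vacuous. The
  residual clipping bias at δ = 0.2 is ≈ −0.01 to −0.03, within the
  ±0.05 recovery check.
* **Anchored screens:** 198 compounds × 3 anchors × 6 doses (3,564
  combination wells per cell line per replicate). The anchor truth is a
  fixed potent inhibitor (ec50 50 nM, einf 0.02, h 1.3). Library truths
  span log10 ec50 ~ U(0.5, 5.5) and einf ~ U(0.1, 0.7), so a realistic
  fraction of the library is inactive in range. Anchor-alone margins
  are laid out like plate controls (8 wells per replicate per anchor
  dose): the margin is subtracted from every compound's excess, so an
  under-replicated margin would shift the whole screen's Bliss scores
  coherently with a single noise draw.
* **Sensitivity matrices:** AUC = compound base U(0.4, 0.9) + cell-line
  offset N(0, 0.05) + per-(line, compound) biological heterogeneity
  N(0, 0.12) + pediatric × pathway shift + assay noise, truncated to
  [0, 1]. The biological term gives each compound a realistic
  across-line AUC spread (sd ≈ 0.14, matching large panels); without it
  a continuous-covariate biomarker analysis would have almost no
  covariate variance to correlate against.
* **Expression:** planted-set genes follow −β·AUC + N(0, 1) (higher
  expression in sensitive lines for β > 0); background genes are pure
  noise. Planted sets must be disjoint.

What these simulations do *not* emulate: plate-geometry artifacts and
edge effects, dose-dependent (rather than uniform) synergy, correlated
gene-expression covariance structure, heavy-tailed or heteroscedastic
assay noise, and any real pharmacology. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
noise model, not robustness to every failure mode of real screens.

## Null behavior of the strict Bliss hit rule

Under the null (no planted synergy) the average Bliss excess over the
18 combination cells of one compound is a mean of mean-zero noise plus
a small negative bias from clipping near-inactive library margins
(≈ −0.006 at σ = 0.05). Its sampling sd is ≈ 0.012, so the strict
"average Bliss > 0" rule fires for roughly Φ(−0.006/0.012) ≈ 30% of
truly independent compounds. Both the bias and the sd scale linearly
with σ, so no replicate count or noise rescaling changes that ratio:
a strict zero threshold on a noisy mean is intrinsically a
high-false-positive screen criterion (it is a *candidate-generation*
rule, not an inferential one), and the measured false-positive rate is
reported alongside hit counts wherever the rule is applied.

## Problem sizes and run parameters

The default pipeline design (3 cell lines, 60-compound anchored
library, 240-line × 198-compound AUC matrix, 1,000 genes,
n_perm = 1,000) exercises every stage in about half a minute and is
the package's chosen demonstration scale; every size is a config key
and the property benchmarks run the full stated designs (198-compound
screens, 2,000-gene biomarker analyses, 200-set type-I checks).

## Known limitations

* The 4PL fallback metrics (interpolated IC50, observed-point AUC) are
  biased for very noisy flat-ish curves; fits are flagged so callers
  can filter.
* Permutation p-values are granular at 2/n_perm; BH-adjusted calls near
  a threshold need n_perm sized accordingly.
* ΔEmax under the default untreated-control normalization mixes the
  anchor's own effect into the combination effect (see above); use the
  anchor-normalized mode when that matters.
* The Bliss model treats inhibition as a probability; cytostatic
  effects measured by metabolic assays violate that reading, as they do
  for any Bliss-based screen analysis.
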