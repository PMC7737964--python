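# Methods

## Model and estimation

Each metabolite is analyzed independently with the linear mixed model

    Y_ijkl = μ + α_k + γ_l + (αγ)_kl + b_j(kl) + e_ijkl,

`b ~ N(0, σ²_pen I)` iid across pens, `e ~ N(0, σ²_e I)`. The random pen
term is specialized to a single iid variance component: with one nested
grouping factor this is the standard structure, and it is the only one the
package fits (no AR(1)/unstructured covariances, no repeated measures,
no ANCOVA). Rows whose response is missing are deleted casewise per
metabolite before the design is built.

Fixed effects use sum-to-zero (deviation) coding throughout, so with every
factorial cell observed the Wald block test of a coefficient group is the
Type III test of that effect — that equivalence is the package's working
definition of Type III. If a metabolite's deletions empty a cell or leave a
factor with one level, that metabolite is flagged and skipped, never the run.

REML estimation profiles β and σ²_e out of the restricted likelihood,
leaving a one-dimensional criterion in the variance ratio θ = σ²_pen/σ²_e,
maximized by bounded scalar search on log θ over [1e-8, 1e6] (tolerance
1e-12 on log θ) with an explicit comparison against the θ = 0 boundary.
This is globally robust, needs no starting values, and never produces a
negative variance. On balanced data the estimates equal the closed-form
nested-ANOVA estimators to 1e-6 relative (tested), and they match both
statsmodels MixedLM and lme4 on fixtures.

## Small-sample inference

The GLS covariance Φ = (XᵀV⁻¹X)⁻¹ understates uncertainty because the
variance components are estimated. The Kenward-Roger adjustment used here
is first-order moment matching: Φ is inflated with the inverse expected
REML information of (σ²_pen, σ²_e), and each hypothesis Lβ = 0 gets a scale
factor and a fractional denominator df from matching the first two moments
of the Wald statistic to a scaled F. Because V is linear in both variance
components, the second-derivative terms vanish and no further correction
applies. Numerical notes:

* Contrast covariances LΦ_A Lᵀ are solved with a condition-number guard at
  1e12; past it the contrast is reported non-estimable.
* A singular information matrix (degenerate designs) falls back to the
  unadjusted covariance with Satterthwaite df and a warning.
* `ddf_method="satterthwaite"` is available as an alternative; for multi-df
  effects it averages eigen-contrast df. Both methods reproduce the
  classical df (pens − cells) in balanced nested designs (tested).
* At the boundary σ̂²_pen = 0 the adjustment is applied with the information
  as computed, mirroring how PROC MIXED-style software proceeds.

For single-df hypotheses the moment matching makes the scale factor unity
and the scaled F equals t² with the adjusted SE, so a two-level factor's
ANOVA p, its margin-difference p, and the Tukey-Kramer-adjusted p with
family size 2 are all identical — asserted at 1e-10 in the tests and
visible in the consolidated output.

LSmeans are cell means (rows of the coded design) and their unweighted
margins; CIs use the adjusted SE with the per-contrast matched df. The
Tukey-Kramer adjustment evaluates the studentized-range tail at √2·|t| with
k = family size; Bonferroni multiplies by the number of comparisons in the
(possibly restricted) family. When the interaction is the finding of
interest, restricting the cell-mean family to the simple effects of interest
(`cell_comparisons`) and using Bonferroni sized by that count avoids the
overpenalization of all-pairs Tukey on 6 comparisons.

## Transformations

One transformation code applies to every metabolite in a run: 0 none,
1 natural log (default — peak areas are positive and right-skewed),
2 square root. "Log" is implemented as natural log; any fixed base yields
identical p-values and back-transformed means, so the choice is cosmetic.
Per-metabolite transformation is supported programmatically via rerunning on
an edited table with code 0, exactly as the original workflow prescribes; an
override map was considered and deliberately left out of the CLI. Box-Cox
selection is out of scope.

## Diagnostics and multiplicity

Normality tests run on the marginal residuals y − Xβ̂ (random effects not
subtracted), matching the residual output the consolidated table mirrors.
Kolmogorov-Smirnov uses the Lilliefors variant since location and scale are
estimated; its p is reported capped at 0.15, the convention of the tables
the output imitates (the raw value is kept internally). QQ plot data uses
Blom plotting positions (i − 3/8)/(n + 1/4).

Across metabolites, each effect is its own adjustment family (three
families for the two-way model), matching the per-effect adjusted columns of
the output; the family size counts only non-missing p-values. BH and
Bonferroni are implemented in-package (ties, clipping and missing-value
semantics pinned by tests against hand-computed values and statsmodels).

## Synthetic data

The generator draws log-intensities from exactly the fitted model: a 2×2
factorial, pens nested in cells (default 4/3/4/3 pens of 2 animals with two
singleton pens, i.e. 26 samples in cells of 8/5/8/5 — the motivating study's
structure), 218 metabolites, per-metabolite baselines N(8, 2²) on the log
scale, σ²_pen = 0.1, σ²_e = 0.25, missingness 0.5% written as ".". Those
defaults are the package's standing study conditions: variances of this size
give intra-pen correlation ≈ 0.29, typical of littermate/pen designs, and
effect sizes are zero unless set. Because intensities are exponentiated
normals, the log transform is exactly right for them; tests passing on this
generator therefore demonstrate correctness of the machinery, not robustness
to real-data violations (heavy tails, metabolite-metabolite correlation,
intensity-dependent missingness — none of which are emulated).

## Problem sizes in the checks

The null-calibration fixture runs 30 replicate studies of 100 metabolites
(9,000 fits per effect), enough for a 99% binomial band of ±0.010 around the
0.05 type-I target and a Monte-Carlo sd of ~0.023 on the mean BH
false-discovery proportion over 90 families. Variance-component recovery
averages metabolites at 200 pens and asserts 3-sd windows; single-fit
windows use ~2.5 sd, reflecting that one σ̂²_pen at 200 pens of 2 animals
still has sd ≈ 0.024. The acceptance script analyzes two full-size
(26 × 218) studies end to end.

## Known limitations

* One random term only; the nesting declaration is implicit (units are keyed
  jointly with their treatment cell, so reused pen labels are distinct).
* Exact reproduction of the published liver-study tables requires the
  journal's supplementary dataset (placed at `data/S1_Data.csv`); the
  corresponding test fails with a pointer when the file is absent.
* The consolidated CSV writes missing fields as "."; reading it back with
  generic CSV tools needs that token declared as NA.
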