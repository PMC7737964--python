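# polynova

Per-metabolite linear mixed models for metabolomics studies with a two-way
factorial treatment structure and a hierarchical (nested) design.

## The problem

Untargeted metabolomics assays routinely quantify hundreds of metabolite peak
areas per sample. When the samples come from a designed animal experiment —
say a 2×2 factorial of diet and probiotic supplementation, with animals
housed in pens nested inside the treatment cells — the right per-metabolite
analysis is not a t-test but a linear mixed model that carries the pen as a
random effect, plus multiplicity control both *within* a metabolite (pairwise
treatment comparisons) and *across* metabolites (hundreds of simultaneous
ANOVAs). polynova automates that whole workflow and consolidates the results
into one sortable table, one row per metabolite.

## The model

For each metabolite, on the transformed scale (natural log by default):

```
Y_ijkl = μ + α_k + γ_l + (αγ)_kl + b_j(kl) + e_ijkl
```

where `α_k` and `γ_l` are the fixed effects of the two crossed treatments,
`(αγ)_kl` their interaction, `b_j(kl) ~ N(0, σ²_pen)` the random effect of
pen `j` nested in treatment cell `(k,l)`, and `e_ijkl ~ N(0, σ²_e)` the
residual. Per metabolite, polynova

1. fits `(σ²_pen, σ²_e)` by REML (profiled one-dimensional search over the
   variance ratio — no starting values, exact boundary handling);
2. runs Type III F tests of both main effects and the interaction with the
   Kenward-Roger small-sample adjustment (inflated fixed-effect covariance
   and matched fractional denominator df);
3. computes least-squares means for the treatment margins and cells, with
   confidence intervals back-transformed to the measurement scale;
4. tests all pairwise LSmean differences, adjusted within-family by
   Tukey-Kramer (studentized range; exact for all-pairs, and identical to
   the raw p when a factor has only two levels) or Bonferroni;
5. tests residual normality (Shapiro-Wilk and Lilliefors/Kolmogorov-Smirnov)
   and writes QQ / fitted-vs-residual plot data;
6. adjusts each effect's ANOVA p-values across metabolites by
   Benjamini-Hochberg FDR (default) or Bonferroni.

The implementation reproduces lme4 + pbkrtest + emmeans
(`lmer`, KR-adjusted `anova`, `emmeans(..., mode="kenward-roger")`) to
printed precision on matched fixtures; the test suite pins those values.

## Worked example

```python
from polynova import ModelSpec, SimDesign, analyze_table, simulate

# a synthetic 26-sample study: 2x2 factorial, pens of 2 animals nested in
# the cells, 6 metabolites, diet shifting log intensity by +/-0.5
design = SimDesign(seed=11, n_metabolites=6, effect_factor2=0.5)
table, truth = simulate(design)

spec = ModelSpec(factor1="Trx1", factor2="Trx2", random_unit="pen")
rows, results = analyze_table(table, spec)
print(rows[["Response", "Pvalue_Trx1", "Pvalue_Trx2", "AdjPvalue_Trx2",
            "Pvalue_Inter", "LS_CON", "LS_HFF",
            "TukeyD_Trx2_CON_HFF"]].round(4).to_string(index=False))
```

```
Response  Pvalue_Trx1  Pvalue_Trx2  AdjPvalue_Trx2  Pvalue_Inter     LS_CON     LS_HFF  TukeyD_Trx2_CON_HFF
  met004       0.0479       0.0027          0.0027        0.1467  1651.4005   676.2691               0.0027
  met002       0.1754       0.0027          0.0027        0.0323 59819.8341 24661.6646               0.0027
  met005       0.5238       0.0010          0.0020        0.6411  2666.6627   621.2876               0.0010
  met006       0.5552       0.0010          0.0020        0.9904  1906.7248   743.2614               0.0010
  met001       0.6350       0.0025          0.0027        0.3952  5943.8836  2651.6386               0.0025
  met003       0.8157       0.0005          0.0020        0.5574 61103.5993 20630.0809               0.0005
```

Every metabolite shows the simulated diet effect (raw and FDR-adjusted
`Pvalue_Trx2` small; the back-transformed diet LSmeans `LS_CON` vs `LS_HFF`
differ by roughly `exp(2 × 0.5) ≈ e`), while the probiotic and interaction
p-values behave like noise. Rows are sorted by the first treatment's raw
p-value; because both factors have two levels, each factor's ANOVA p equals
its margin-comparison p (`TukeyD_Trx2_CON_HFF` = `Pvalue_Trx2`).

The same analysis runs from the shell:

```sh
polynova simulate --out sim.csv --seed 11 --n-metabolites 6 --effect-factor2 0.5
polynova twoway --input sim.csv --factor1 Trx1 --factor2 Trx2 \
    --random "pen(Trx1*Trx2)" --exclude pig --exclude pen \
    --normtrans 1 --pval-adjust fdr --pairwise-adjust tukey \
    --respath results --name demo
polynova oneway --input sim.csv --factor Trx1 --random pen \
    --exclude pig --exclude pen --ignore Trx2 --respath results --name demo1w
```

Real data goes in as a wide CSV — one row per sample, columns for the sample
identifiers and the two treatments, one column per metabolite, missing peaks
marked `.` — with `--exclude`/`--ignore` declaring the non-response columns.

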