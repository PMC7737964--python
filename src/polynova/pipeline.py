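"""Orchestration: per-metabolite model fitting and the consolidated results table.

For every metabolite the pipeline transforms the response, builds the design,
fits the mixed model by REML, runs Kenward-Roger Type III tests, computes
LSmeans with confidence intervals (margins and cells), pairwise differences
with within-metabolite multiplicity adjustment, and residual normality
diagnostics.  Raw ANOVA p-values are then adjusted across metabolites (FDR or
Bonferroni, one family per effect), rows are sorted by the first treatment
variable's raw p-value, and everything is written as one consolidated CSV or
one CSV per result component.

A failing metabolite (transform domain violation, empty cell, non-converged
fit...) never aborts the run: its row is kept with missing fields and a
status code.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics, means, multitest
from .errors import DesignError, InputError, NotEstimableError, PolynovaError, TransformDomainError
from .inference import kenward_roger, type3_test
from .io import FeatureTable, export_results, read_wide_table, to_long, validate_names
from .mixed_model import ModelSpec, build_design, fit_reml
from .transforms import TransformCode, apply_transform

__all__ = ["RunConfig", "MetaboliteResult", "analyze_table",
           "run_two_way", "run_one_way"]

logger = logging.getLogger("polynova")

_ADJ_PREFIX = {"tukey_kramer": "TukeyD", "bonferroni": "BonfD"}


@dataclass
class RunConfig:
    """Everything a run needs; mirrors the macro-variable surface."""

    input: str | Path
    treatment_var1: str
    treatment_var2: str | None = None
    random_statement: str | None = None     # e.g. "pen(Trx1*Trx2)" or "pen"
    exclude_vars: tuple[str, ...] = ()
    ignore_vars: tuple[str, ...] = ()
    normtrans: int = 1                      # 0 none, 1 log, 2 sqrt
    pval_adjust: str = "fdr"                # across metabolites
    pairwise_adjust: str = "tukey_kramer"   # within metabolite
    ddf_method: str = "kenward_roger"
    respath: str | Path = "results"
    normgraphpath: str | Path | None = None
    fitgraphpath: str | Path | None = None
    name: str = "polynova_results"
    singlefile: bool = True
    render_plots: bool = False
    strict_names: bool = False
    cell_comparisons: tuple[tuple[str, str], ...] | None = None
    seed: int | None = None
    round_digits: int | None = None

    @property
    def random_unit(self) -> str | None:
        if not self.random_statement:
            return None
        return self.random_statement.split("(")[0].strip()

    def model_spec(self) -> ModelSpec:
        return ModelSpec(factor1=self.treatment_var1,
                         factor2=self.treatment_var2,
                         interaction=self.treatment_var2 is not None,
                         random_unit=self.random_unit,
                         transform=TransformCode(self.normtrans),
                         ddf_method=self.ddf_method,
                         pairwise_adjust=self.pairwise_adjust,
                         feature_adjust=self.pval_adjust)


@dataclass
class MetaboliteResult:
    """Full per-metabolite output kept for programmatic access."""

    name: str
    status: str
    fit: object | None = None
    kr: object | None = None
    tests: dict = field(default_factory=dict)
    lsmeans: dict = field(default_factory=dict)
    pairwise: dict = field(default_factory=dict)
    normality: object | None = None
    seconds: float = 0.0


def _status_of(exc: Exception) -> str:
    if isinstance(exc, TransformDomainError):
        return "transform-domain"
    if isinstance(exc, DesignError):
        return "design-error"
    if isinstance(exc, NotEstimableError):
        return "not-estimable"
    return "error"


def _analyze_one(name: str, data: pd.DataFrame, spec: ModelSpec,
                 cell_restrict=None) -> MetaboliteResult:
    t0 = time.perf_counter()
    res = MetaboliteResult(name=name, status="ok")
    try:
        data = data.copy()
        data["value"] = apply_transform(data["value"].to_numpy(),
                                        spec.transform, name=name)
        design = build_design(data, spec)
        fit = fit_reml(design)
        res.fit = fit
        if not fit.converged:
            res.status = "no-convergence"
            return res
        kr = kenward_roger(fit)
        res.kr = kr
        for effect in spec.effects:
            try:
                res.tests[effect] = type3_test(fit, kr, effect)
            except NotEstimableError:
                res.tests[effect] = None
        margins = [spec.factor1] + ([spec.factor2] if spec.factor2 else [])
        for scope in margins + (["cell"] if spec.factor2 else []):
            res.lsmeans[scope] = means.lsmeans(fit, kr, scope)
        for fam in margins:
            res.pairwise[fam] = means.pairwise(fit, kr, fam,
                                               method=spec.pairwise_adjust)
        if spec.factor2:
            res.pairwise["cell"] = means.pairwise(
                fit, kr, "cell", method=spec.pairwise_adjust,
                restrict=cell_restrict)
        res.normality = diagnostics.normality_tests(fit)
    except (PolynovaError, np.linalg.LinAlgError) as exc:
        res.status = _status_of(exc)
        logger.warning("metabolite %s failed (%s): %s", name, res.status, exc)
    res.seconds = time.perf_counter() - t0
    return res


def _pair_columns(spec: ModelSpec, results: list[MetaboliteResult]):
    """Union of pairwise labels per family, in first-seen order."""
    fams = [spec.factor1] + ([spec.factor2] if spec.factor2 else [])
    if spec.factor2:
        fams.append("cell")
    labels: dict[str, list[str]] = {f: [] for f in fams}
    for r in results:
        for f in fams:
            for cmp_ in r.pairwise.get(f, []):
                if cmp_.label not in labels[f]:
                    labels[f].append(cmp_.label)
    return labels


def _family_tag(spec: ModelSpec, family: str) -> str:
    if family == "cell":
        return f"{spec.factor1}_{spec.factor2}"
    return family


def consolidate(results: list[MetaboliteResult], spec: ModelSpec) -> pd.DataFrame:
    """Assemble one row per metabolite in the published column order."""
    eff_cols = []
    for effect in spec.effects:
        tag = "Inter" if effect == "interaction" else effect
        eff_cols.append((effect, f"Pvalue_{tag}", f"AdjPvalue_{tag}"))
    pair_labels = _pair_columns(spec, results)
    adj_prefix = _ADJ_PREFIX[spec.pairwise_adjust]

    ls_labels: dict[str, list[str]] = {}
    for r in results:
        for scope, lst in r.lsmeans.items():
            ls_labels.setdefault(scope, [])
            for e in lst:
                if e.label not in ls_labels[scope]:
                    ls_labels[scope].append(e.label)

    rows = []
    for r in results:
        row: dict[str, object] = {
            "Response": r.name,
            "Transformation": spec.transform.label,
            "Shapiro_Wilk": np.nan, "Kolmogorov": np.nan,
        }
        if r.normality is not None:
            row["Shapiro_Wilk"] = r.normality.shapiro_p
            row["Kolmogorov"] = r.normality.ks_p_reported
        for effect, raw_col, adj_col in eff_cols:
            test = r.tests.get(effect)
            row[raw_col] = test.p_raw if test else np.nan
            row[adj_col] = np.nan
        for scope, lab_list in ls_labels.items():
            found = {e.label: e for e in r.lsmeans.get(scope, [])}
            for lab in lab_list:
                e = found.get(lab)
                row[f"LS_{lab}"] = e.bt_estimate if e else np.nan
                row[f"CI_Lower_{lab}"] = e.bt_lower if e else np.nan
                row[f"CI_Upper_{lab}"] = e.bt_upper if e else np.nan
        for fam, lab_list in pair_labels.items():
            tag = _family_tag(spec, fam)
            found = {c.label: c for c in r.pairwise.get(fam, [])}
            for lab in lab_list:
                c = found.get(lab)
                row[f"P_valueD_{tag}_{lab}"] = c.p_raw if c else np.nan
        for fam, lab_list in pair_labels.items():
            tag = _family_tag(spec, fam)
            found = {c.label: c for c in r.pairwise.get(fam, [])}
            for lab in lab_list:
                c = found.get(lab)
                row[f"{adj_prefix}_{tag}_{lab}"] = c.p_adjusted if c else np.nan
        row["status"] = r.status
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_table(table: FeatureTable, spec: ModelSpec,
                  cell_restrict=None) -> tuple[pd.DataFrame, list[MetaboliteResult]]:
    """Run the per-metabolite analysis over a FeatureTable (no file IO).

    Returns the consolidated table (sorted by the first treatment's raw
    ANOVA p, failures last) and the per-metabolite result objects in input
    order.
    """
    long = to_long(table)
    results = []
    for name, group in long.groupby("response_name", sort=False):
        results.append(_analyze_one(name, group, spec, cell_restrict))
    rows = consolidate(results, spec)

    raw_cols = {e: f"Pvalue_{'Inter' if e == 'interaction' else e}"
                for e in spec.effects}
    raw = rows[[raw_cols[e] for e in spec.effects]]
    raw.columns = list(spec.effects)
    adj = multitest.adjust_all_effects(raw, method=spec.feature_adjust)
    for e in spec.effects:
        tag = "Inter" if e == "interaction" else e
        rows[f"AdjPvalue_{tag}"] = adj[e].to_numpy()
        for r, p in zip(results, adj[e].to_numpy()):
            if r.tests.get(e) is not None:
                r.tests[e].p_adjusted = float(p)

    sort_col = f"Pvalue_{spec.factor1}"
    rows = rows.sort_values(sort_col, kind="stable",
                            na_position="last").reset_index(drop=True)
    return rows, results


def _cell_restrict(pairs):
    if pairs is None:
        return None
    wanted = {frozenset(p) for p in pairs}
    return lambda a, b: frozenset(("_".join(a), "_".join(b))) in wanted


def _run(config: RunConfig, spec: ModelSpec) -> tuple[pd.DataFrame, list[MetaboliteResult]]:
    t0 = time.perf_counter()
    table = read_wide_table(config.input, config.treatment_var1,
                            config.treatment_var2,
                            exclude_vars=config.exclude_vars,
                            ignore_vars=config.ignore_vars)
    report = validate_names(table.metabolite_names)
    if not report.is_clean:
        msg = "; ".join(f"{n}: {why}" for n, why in report.violations[:10])
        if config.strict_names:
            raise InputError(f"variable-name violations: {msg}")
        logger.warning("variable-name violations (proceeding): %s", msg)

    rows, results = analyze_table(table, spec,
                                  cell_restrict=_cell_restrict(config.cell_comparisons))

    for r in results:
        if r.fit is not None and r.status in ("ok", "no-convergence"):
            if config.normgraphpath or config.fitgraphpath:
                diagnostics.plot_data(r.fit, r.name,
                                      normgraphpath=config.normgraphpath,
                                      fitgraphpath=config.fitgraphpath,
                                      render=config.render_plots)

    out = rows
    if config.round_digits is not None:
        num = out.select_dtypes(include=[float]).columns
        out = out.copy()
        out[num] = out[num].round(config.round_digits)
    export_results(out, config.name, config.singlefile, config.respath,
                   sort_by=f"Pvalue_{spec.factor1}")
    n_ok = sum(r.status == "ok" for r in results)
    logger.info("analyzed %d metabolites (%d ok, %d failed) in %.1fs",
                len(results), n_ok, len(results) - n_ok,
                time.perf_counter() - t0)
    return rows, results


def run_two_way(config: RunConfig) -> tuple[pd.DataFrame, list[MetaboliteResult]]:
    """Full two-way factorial analysis from a wide CSV to result files."""
    if config.treatment_var2 is None:
        raise InputError("two-way analysis needs treatment_var2")
    return _run(config, config.model_spec())


def run_one_way(config: RunConfig) -> tuple[pd.DataFrame, list[MetaboliteResult]]:
    """One-way analysis: a single treatment factor, optional nested unit."""
    cfg_spec = ModelSpec(factor1=config.treatment_var1, factor2=None,
                         interaction=False, random_unit=config.random_unit,
                         transform=TransformCode(config.normtrans),
                         ddf_method=config.ddf_method,
                         pairwise_adjust=config.pairwise_adjust,
                         feature_adjust=config.pval_adjust)
    config.treatment_var2 = None
    return _run(config, cfg_spec)
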