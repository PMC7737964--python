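import numpy as np
import pandas as pd
import pytest

from polynova import ModelSpec, TransformCode
from polynova.errors import DesignError
from polynova.mixed_model import build_design, fit_reml, sum_to_zero_codes
from conftest import balanced_table, long_one


SPEC = ModelSpec(factor1="Trx1", factor2="Trx2", random_unit="pen",
                 transform=TransformCode.NONE)


def _log_design(table, name="met001", spec=SPEC):
    df = long_one(table, name)
    df["value"] = np.log(df["value"])
    return build_design(df, spec)


def nested_anova_varcomp(df, unit="pen"):
    """Closed-form REML for the balanced nested design: the residual variance
    is the within-unit mean square and the unit variance is
    (between-unit-within-cell MS - within MS) / (animals per unit)."""
    cell = df["Trx1"].astype(str) + ":" + df["Trx2"].astype(str)
    pen_mean = df.groupby(unit)["value"].transform("mean")
    cell_mean = df.groupby(cell)["value"].transform("mean")
    n = len(df)
    pens = df[unit].nunique()
    cells = cell.nunique()
    K = n // pens
    ms_within = float(((df["value"] - pen_mean) ** 2).sum() / (n - pens))
    ms_pen = float(((pen_mean - cell_mean) ** 2).sum() / (pens - cells))
    return max(0.0, (ms_pen - ms_within) / K), ms_within


def test_sum_to_zero_codes_shape_and_balance():
    C = sum_to_zero_codes(3)
    assert C.shape == (3, 2)
    np.testing.assert_allclose(C.sum(axis=0), 0.0)


def test_build_design_dimensions_and_slices(oracle_table):
    design = _log_design(oracle_table[0])
    assert design.X.shape == (26, 4)
    assert design.Z.shape == (26, 14)
    np.testing.assert_allclose(design.Z.sum(axis=1), 1.0)
    assert [design.effect_slices[e] for e in ("Trx1", "Trx2", "interaction")] \
        == [slice(1, 2), slice(2, 3), slice(3, 4)]
    assert design.cells == [("N", "CON"), ("N", "HFF"), ("P", "CON"), ("P", "HFF")]


def test_casewise_deletion_drops_rows(oracle_table):
    df = long_one(oracle_table[0])
    df["value"] = np.log(df["value"])
    df.loc[df.index[3], "value"] = np.nan
    design = build_design(df, SPEC)
    assert design.X.shape[0] == 25
    assert 3 not in design.row_index


def test_single_level_factor_is_a_design_error():
    table, _ = balanced_table(seed=5)
    df = long_one(table)
    df["Trx1"] = "N"
    with pytest.raises(DesignError, match="at least 2"):
        build_design(df, SPEC)


def test_empty_cell_is_a_design_error():
    table, _ = balanced_table(seed=5)
    df = long_one(table)
    df.loc[(df.Trx1 == "N") & (df.Trx2 == "CON"), "value"] = np.nan
    with pytest.raises(DesignError, match="empty factorial cell"):
        build_design(df, SPEC)


@pytest.mark.parametrize("seed", [11, 12, 13])
def test_reml_matches_closed_form_on_balanced_data(seed):
    table, _ = balanced_table(seed=seed, pens_per_cell=3, animals=3)
    design = _log_design(table)
    fit = fit_reml(design)
    df = long_one(table)
    df["value"] = np.log(df["value"])
    s2_pen, s2_e = nested_anova_varcomp(df)
    assert fit.varcomp.sigma2_resid == pytest.approx(s2_e, rel=1e-6)
    assert fit.varcomp.sigma2_unit == pytest.approx(s2_pen, rel=1e-6, abs=1e-10)


def test_reml_matches_statsmodels_mixedlm(oracle_table):
    sm = pytest.importorskip("statsmodels.formula.api")
    table, _ = oracle_table
    df = long_one(table)
    df["value"] = np.log(df["value"])
    fit = fit_reml(build_design(df, SPEC))
    df["unit"] = (df["Trx1"].astype(str) + df["Trx2"].astype(str)
                  + df["pen"].astype(str))
    mod = sm.mixedlm("value ~ C(Trx1) * C(Trx2)", df, groups=df["unit"]).fit(reml=True)
    assert fit.varcomp.sigma2_unit == pytest.approx(
        float(mod.cov_re.iloc[0, 0]), rel=1e-4)
    assert fit.varcomp.sigma2_resid == pytest.approx(float(mod.scale), rel=1e-4)


def test_optimum_beats_a_grid(oracle_table):
    from polynova.mixed_model import _profile_loglik
    design = _log_design(oracle_table[0])
    fit = fit_reml(design)
    best = fit.reml_loglik
    thetas = np.concatenate([[0.0], np.geomspace(1e-4, 1e3, 50)])
    grid = [_profile_loglik(design, th) for th in thetas]
    assert best >= max(grid) - 1e-8


def test_zero_pen_variance_estimates_hit_the_boundary():
    hits = 0
    for seed in range(8):
        table, _ = balanced_table(seed=100 + seed, sigma2_pen=0.0)
        fit = fit_reml(_log_design(table))
        assert fit.varcomp.sigma2_unit >= 0.0
        hits += fit.varcomp.sigma2_unit == 0.0
    assert hits >= 3  # boundary reached with positive probability


def test_rescaling_y_rescales_components_quadratically(oracle_table):
    design = _log_design(oracle_table[0])
    fit = fit_reml(design)
    c = 3.7
    scaled = build_design(
        pd.DataFrame({"Trx1": long_one(oracle_table[0])["Trx1"],
                      "Trx2": long_one(oracle_table[0])["Trx2"],
                      "pen": long_one(oracle_table[0])["pen"],
                      "value": design.y * c}).assign(),
        SPEC)
    # rebuild with identical rows: rows align because nothing is missing
    fit_c = fit_reml(scaled)
    assert fit_c.varcomp.sigma2_unit == pytest.approx(
        c ** 2 * fit.varcomp.sigma2_unit, rel=1e-5)
    assert fit_c.varcomp.sigma2_resid == pytest.approx(
        c ** 2 * fit.varcomp.sigma2_resid, rel=1e-5)
    np.testing.assert_allclose(fit_c.beta, c * fit.beta, rtol=1e-6)


def test_no_random_term_reduces_to_ols(oracle_table):
    table, _ = oracle_table
    spec = ModelSpec(factor1="Trx1", factor2="Trx2", random_unit=None,
                     transform=TransformCode.NONE)
    design = _log_design(table, spec=spec)
    fit = fit_reml(design)
    X, y = design.X, design.y
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    np.testing.assert_allclose(fit.beta, beta_ols, rtol=1e-10)
    resid = y - X @ beta_ols
    s2 = resid @ resid / (len(y) - X.shape[1])
    assert fit.varcomp.sigma2_resid == pytest.approx(s2, rel=1e-12)
    assert fit.varcomp.sigma2_unit == 0.0


def test_parameter_recovery_with_many_pens():
    """With 200 pens the REML estimates concentrate near the truth.

    A single fit of sigma2_pen at this size still carries a sampling sd of
    about 0.024 (the pen means mix sigma2_pen with sigma2_resid / 2), so the
    check averages independent metabolites, shrinking the Monte-Carlo sd to
    about 0.008, and asserts a 3-sd window around the truth."""
    table, _ = balanced_table(seed=77, pens_per_cell=50, animals=2, m=10,
                              sigma2_pen=0.1, sigma2_resid=0.25)
    fits = [fit_reml(_log_design(table, name)) for name in table.metabolite_names]
    mean_pen = np.mean([f.varcomp.sigma2_unit for f in fits])
    mean_res = np.mean([f.varcomp.sigma2_resid for f in fits])
    assert mean_pen == pytest.approx(0.1, abs=0.025)
    assert mean_res == pytest.approx(0.25, abs=0.025)
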