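import itertools

import numpy as np
import pytest
from scipy import stats

from polynova import ModelSpec, TransformCode
from polynova.errors import NotEstimableError, PolynovaError
from polynova.inference import type3_test
from polynova.means import lsmeans, pairwise, tukey_kramer_p


# Frozen emmeans (kenward-roger mode) reference for the oracle fixture:
# margins on the log scale with adjusted SE, KR df and 95% CI.
R_MARGINS = {
    ("Trx1", "N"): (8.467366, 0.14523959, 10.02, 8.143840, 8.790892),
    ("Trx1", "P"): (8.810740, 0.14523959, 10.02, 8.487214, 9.134265),
    ("Trx2", "CON"): (9.074594, 0.12755649, 8.88, 8.785452, 9.363736),
    ("Trx2", "HFF"): (8.203512, 0.16099199, 10.84, 7.848520, 8.558504),
}
# cell differences: estimate, SE, df, raw p, Tukey p (family of 4 means)
R_CELL_PAIRS = {
    ("N_CON", "N_HFF"): (0.8455692, 0.2904792, 10.02, 0.0155, 0.0632),
    ("N_CON", "P_CON"): (-0.3688864, 0.2551130, 8.88, 0.1825, 0.5050),
    ("N_CON", "P_HFF"): (0.5277078, 0.2904792, 10.02, 0.0993, 0.3209),
    ("N_HFF", "P_CON"): (-1.2144556, 0.2904792, 10.02, 0.0019, 0.0085),
    ("N_HFF", "P_HFF"): (-0.3178614, 0.3219840, 10.84, 0.3451, 0.7596),
    ("P_CON", "P_HFF"): (0.8965942, 0.2904792, 10.02, 0.0115, 0.0478),
}


def test_margin_lsmeans_match_emmeans(oracle_fit):
    fit, kr = oracle_fit
    for scope in ("Trx1", "Trx2"):
        for est in lsmeans(fit, kr, scope):
            ref = R_MARGINS[(scope, est.levels[0])]
            assert est.estimate == pytest.approx(ref[0], abs=5e-6)
            assert est.se == pytest.approx(ref[1], abs=5e-8)
            assert est.df == pytest.approx(ref[2], abs=5e-3)
            assert est.lower == pytest.approx(ref[3], abs=5e-6)
            assert est.upper == pytest.approx(ref[4], abs=5e-6)


def test_cell_pairwise_matches_emmeans(oracle_fit):
    fit, kr = oracle_fit
    got = {(("_".join(c.left)), ("_".join(c.right))): c
           for c in pairwise(fit, kr, "cell", method="tukey_kramer")}
    assert len(got) == 6  # C(4,2) comparisons for the 2x2 cells
    for key, (diff, se, df, p_raw, p_tukey) in R_CELL_PAIRS.items():
        c = got[key]
        assert c.diff == pytest.approx(diff, abs=5e-7)
        assert c.se == pytest.approx(se, abs=5e-7)
        assert c.df == pytest.approx(df, abs=5e-3)
        assert c.p_raw == pytest.approx(p_raw, abs=5e-5)
        assert c.p_adjusted == pytest.approx(p_tukey, abs=5e-5)


def test_margin_lsmean_is_average_of_cell_lsmeans(oracle_fit):
    fit, kr = oracle_fit
    cells = {e.levels: e.estimate for e in lsmeans(fit, kr, "cell")}
    for est in lsmeans(fit, kr, "Trx2"):
        lev = est.levels[0]
        avg = np.mean([v for k, v in cells.items() if k[1] == lev])
        assert est.estimate == pytest.approx(avg, rel=1e-10)


def test_back_transform_preserves_cell_ordering(oracle_fit):
    fit, kr = oracle_fit
    cells = lsmeans(fit, kr, "cell")
    order_t = np.argsort([e.estimate for e in cells])
    order_bt = np.argsort([e.bt_estimate for e in cells])
    np.testing.assert_array_equal(order_t, order_bt)
    for e in cells:
        assert e.bt_lower < e.bt_estimate < e.bt_upper


def test_tukey_with_two_means_equals_raw_t():
    for t, df in itertools.product((0.3, 1.1, 2.7), (4.0, 11.5, 24.0)):
        raw = 2.0 * stats.t.sf(t, df)
        assert tukey_kramer_p(t, 2, df) == pytest.approx(raw, abs=1e-10)


def test_tukey_p_is_monotone_in_family_size():
    ps = [tukey_kramer_p(2.2, k, 10.0) for k in (2, 3, 4, 6, 9)]
    assert all(np.diff(ps) > 0)


def test_margin_difference_p_equals_type3_p(oracle_fit):
    """For a two-level factor the margin contrast is the Type III test:
    t^2 = F and the p-values agree at full precision."""
    fit, kr = oracle_fit
    for factor in ("Trx1", "Trx2"):
        cmp_, = pairwise(fit, kr, factor, method="tukey_kramer")
        t3 = type3_test(fit, kr, factor)
        assert cmp_.t ** 2 == pytest.approx(t3.F, rel=1e-10)
        assert cmp_.p_raw == pytest.approx(t3.p_raw, rel=1e-10)
        # with k = 2 the studentized-range adjustment changes nothing
        assert cmp_.p_adjusted == pytest.approx(cmp_.p_raw, abs=1e-10)


def test_bonferroni_family_sizing(oracle_fit):
    fit, kr = oracle_fit
    cells = pairwise(fit, kr, "cell", method="bonferroni")
    for c in cells:
        assert c.p_adjusted == pytest.approx(min(1.0, 6 * c.p_raw), rel=1e-12)
    margin, = pairwise(fit, kr, "Trx1", method="bonferroni")
    assert margin.p_adjusted == pytest.approx(margin.p_raw, rel=1e-12)  # m = 1


def test_cell_comparison_restriction_resizes_bonferroni(oracle_fit):
    fit, kr = oracle_fit
    keep = lambda a, b: a[0] == b[0]  # same probiotic level: simple diet effects
    cells = pairwise(fit, kr, "cell", method="bonferroni", restrict=keep)
    assert len(cells) == 2
    for c in cells:
        assert c.p_adjusted == pytest.approx(min(1.0, 2 * c.p_raw), rel=1e-12)


def test_adjusted_never_below_raw(oracle_fit):
    fit, kr = oracle_fit
    for method in ("tukey_kramer", "bonferroni"):
        for c in pairwise(fit, kr, "cell", method=method):
            assert c.p_adjusted >= c.p_raw - 1e-15
            assert c.p_adjusted <= 1.0


def test_unknown_method_and_degenerate_family(oracle_fit):
    fit, kr = oracle_fit
    with pytest.raises(PolynovaError, match="unknown pairwise"):
        pairwise(fit, kr, "Trx1", method="scheffe")
    with pytest.raises(NotEstimableError):
        pairwise(fit, kr, "cell", restrict=lambda a, b: False)


def test_intercept_only_lsmean_is_gls_mean(oracle_table):
    """A one-way fit's margin means bracket the grand GLS mean and the CI is
    symmetric on the analysis scale."""
    from polynova.inference import kenward_roger
    from polynova.mixed_model import build_design, fit_reml
    from conftest import long_one

    table, _ = oracle_table
    spec = ModelSpec(factor1="Trx1", factor2=None, random_unit="pen",
                     transform=TransformCode.NONE)
    df = long_one(table)
    df["value"] = np.log(df["value"])
    fit = fit_reml(build_design(df, spec))
    kr = kenward_roger(fit)
    for est in lsmeans(fit, kr, "Trx1"):
        assert est.upper - est.estimate == pytest.approx(
            est.estimate - est.lower, rel=1e-10)
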