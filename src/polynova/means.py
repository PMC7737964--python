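"""Least-squares means, confidence intervals and pairwise comparisons.

An LSmean is a linear combination c'beta of the fixed effects that averages
the factorial cell means evenly over the levels of the other factor(s), so
margins are balanced even when cell sizes are not.  Standard errors use the
Kenward-Roger adjusted covariance and per-contrast matched degrees of
freedom; estimates and interval endpoints are mapped back to the measurement
scale for reporting.

Within-metabolite multiplicity over a family of pairwise differences is
handled by the Tukey-Kramer studentized-range adjustment (exact for
all-pairs comparisons; the default for treatment margins) or by Bonferroni
sized by the number of comparisons in the (possibly user-restricted) family,
the recommended choice for simple-effect comparisons among cell means.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import NotEstimableError, PolynovaError
from .inference import KRAdjustment, contrast_test
from .mixed_model import MixedFit, sum_to_zero_codes
from .transforms import back_transform_point_and_interval

__all__ = ["LsmeanEstimate", "PairwiseComparison", "lsmeans", "pairwise",
           "cell_row", "tukey_kramer_p"]


@dataclass
class LsmeanEstimate:
    """One margin or cell LSmean, on both the analysis and the data scale."""

    scope: str                  # factor name for a margin, "cell" for a cell
    levels: tuple[str, ...]
    estimate: float             # analysis (transformed) scale
    se: float
    df: float
    lower: float
    upper: float
    bt_estimate: float          # back-transformed (data) scale
    bt_lower: float
    bt_upper: float

    @property
    def label(self) -> str:
        return "_".join(self.levels)


@dataclass
class PairwiseComparison:
    """A difference of two LSmeans with raw and multiplicity-adjusted p."""

    family: str
    left: tuple[str, ...]
    right: tuple[str, ...]
    diff: float
    se: float
    df: float
    t: float
    p_raw: float
    p_adjusted: float
    method: str

    @property
    def label(self) -> str:
        return "_".join(self.left) + "_" + "_".join(self.right)


def cell_row(fit: MixedFit, cell: tuple[str, ...]) -> np.ndarray:
    """Design row (in the sum-to-zero basis) for one factorial cell mean."""
    design = fit.design
    spec = design.spec
    row = np.zeros(design.p)
    row[0] = 1.0
    factors = [spec.factor1] + ([spec.factor2] if spec.factor2 else [])
    codes = {}
    for f, lev in zip(factors, cell):
        levels = design.levels[f]
        C = sum_to_zero_codes(len(levels))
        i = levels.index(lev)
        codes[f] = C[i, :]
        row[design.effect_slices[f]] = C[i, :]
    if "interaction" in design.effect_slices:
        inter = np.outer(codes[spec.factor1], codes[spec.factor2]).ravel()
        row[design.effect_slices["interaction"]] = inter
    return row


def _scope_rows(fit: MixedFit, scope: str) -> list[tuple[tuple[str, ...], np.ndarray]]:
    """(levels, contrast-row) pairs for a margin or the cell family."""
    design = fit.design
    spec = design.spec
    cells = design.cells
    if scope == "cell":
        if spec.factor2 is None:
            raise NotEstimableError("cell scope requires a two-way model")
        return [(c, cell_row(fit, c)) for c in cells]
    if scope not in design.levels:
        raise NotEstimableError(f"unknown LSmean scope {scope!r}")
    which = 0 if scope == spec.factor1 else 1
    out = []
    for lev in design.levels[scope]:
        rows = [cell_row(fit, c) for c in cells if c[which] == lev]
        out.append(((lev,), np.mean(rows, axis=0)))
    return out


def lsmeans(fit: MixedFit, kr: KRAdjustment, scope: str,
            level: float = 0.95) -> list[LsmeanEstimate]:
    """LSmeans for one factor margin (scope = factor name) or all cells
    (scope = "cell"), with back-transformed point estimates and CIs."""
    alpha = 1.0 - level
    out = []
    for levels, c in _scope_rows(fit, scope):
        est = float(c @ fit.beta)
        se = float(np.sqrt(c @ kr.phi_adj @ c))
        res = contrast_test(fit, kr, c)
        tcrit = float(stats.t.ppf(1 - alpha / 2, res.df))
        lo, hi = est - tcrit * se, est + tcrit * se
        bt_est, bt_lo, bt_hi = back_transform_point_and_interval(
            est, lo, hi, fit.spec.transform)
        out.append(LsmeanEstimate(scope=scope, levels=levels, estimate=est,
                                  se=se, df=res.df, lower=lo, upper=hi,
                                  bt_estimate=bt_est, bt_lower=bt_lo,
                                  bt_upper=bt_hi))
    return out


def tukey_kramer_p(t: float, k: int, df: float) -> float:
    """Studentized-range p for |t| with family size k; equals the raw
    two-sided t probability when k = 2."""
    if k < 2:
        raise PolynovaError("Tukey-Kramer needs at least 2 means in the family")
    return float(stats.studentized_range.sf(np.sqrt(2.0) * abs(t), k, df))


def pairwise(fit: MixedFit, kr: KRAdjustment, family: str,
             method: str = "tukey_kramer",
             restrict=None) -> list[PairwiseComparison]:
    """All pairwise LSmean differences within a family.

    Parameters
    ----------
    family : str
        A factor name (margin comparisons) or "cell".
    method : {"tukey_kramer", "bonferroni"}
        Multiplicity adjustment within the family.
    restrict : callable, optional
        Predicate on (left_levels, right_levels) selecting the comparisons of
        interest; the Bonferroni multiplier follows the restricted count.
    """
    if method not in ("tukey_kramer", "bonferroni"):
        raise PolynovaError(f"unknown pairwise adjustment {method!r}")
    rows = _scope_rows(fit, family)
    if len(rows) < 2:
        raise NotEstimableError(f"family {family!r} has fewer than 2 means")
    pairs = [(a, b) for a, b in itertools.combinations(rows, 2)]
    if restrict is not None:
        pairs = [(a, b) for a, b in pairs if restrict(a[0], b[0])]
        if not pairs:
            raise NotEstimableError("comparison restriction removed every pair")
    k = len(rows)
    m = len(pairs)
    out = []
    for (lev_a, ca), (lev_b, cb) in pairs:
        res = contrast_test(fit, kr, ca - cb)
        if method == "tukey_kramer":
            p_adj = tukey_kramer_p(res.t, k, res.df)
        else:
            p_adj = min(1.0, m * res.p)
        p_adj = max(p_adj, res.p)  # an adjustment never reports below raw
        out.append(PairwiseComparison(family=family, left=lev_a, right=lev_b,
                                      diff=res.estimate, se=res.se, df=res.df,
                                      t=res.t, p_raw=res.p, p_adjusted=p_adj,
                                      method=method))
    return out
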