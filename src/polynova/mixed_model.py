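"""Design construction and REML estimation of the two-variance-component mixed model.

For one metabolite the model is

    y_ijkl = mu + alpha_k + gamma_l + (alpha*gamma)_kl + b_j(kl) + e_ijkl

with crossed fixed treatments alpha and gamma (plus their interaction) and a
random housing-unit effect b nested within the treatment cells,
b ~ N(0, sigma2_unit * I), e ~ N(0, sigma2_resid * I).  Fixed effects are
coded sum-to-zero so that the Wald block test of each term is the Type III
test for factorials with all cells filled.

Estimation profiles both the residual variance and the fixed effects out of
the REML criterion, leaving a one-dimensional maximization over the variance
ratio theta = sigma2_unit / sigma2_resid, which is solved by bounded scalar
search on the log scale.  The ratio parameterization has no starting-value
sensitivity and handles the boundary theta = 0 (no between-unit variance)
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .errors import DesignError
from .transforms import TransformCode

__all__ = ["ModelSpec", "DesignMatrices", "VarianceComponents", "MixedFit",
           "build_design", "fit_reml", "sum_to_zero_codes"]

#: search window for the variance ratio theta = sigma2_unit / sigma2_resid
_THETA_MIN, _THETA_MAX = 1e-8, 1e6
_PROFILE_XTOL = 1e-12


@dataclass
class ModelSpec:
    """Declaration of the fixed factors, random nesting and analysis options."""

    factor1: str
    factor2: str | None = None
    interaction: bool = True
    random_unit: str | None = None
    transform: TransformCode = TransformCode.LOG
    ddf_method: str = "kenward_roger"          # or "satterthwaite"
    pairwise_adjust: str = "tukey_kramer"      # or "bonferroni"
    feature_adjust: str = "fdr"                # or "bonferroni"

    def __post_init__(self) -> None:
        if self.factor2 is not None and self.factor1 == self.factor2:
            raise DesignError("factor1 and factor2 must differ")
        if self.random_unit is not None and self.random_unit in (self.factor1, self.factor2):
            raise DesignError("the random unit cannot also be a fixed factor")
        if self.factor2 is None:
            self.interaction = False
        if self.ddf_method not in ("kenward_roger", "satterthwaite"):
            raise DesignError(f"unknown ddf method {self.ddf_method!r}")

    @property
    def effects(self) -> list[str]:
        eff = [self.factor1]
        if self.factor2 is not None:
            eff.append(self.factor2)
            if self.interaction:
                eff.append("interaction")
        return eff


@dataclass
class DesignMatrices:
    """Aligned model matrices for one metabolite after casewise deletion."""

    X: np.ndarray                       # n x p fixed-effects matrix, full rank
    Z: np.ndarray | None                # n x q random-unit indicators (or None)
    y: np.ndarray                       # transformed response
    row_index: np.ndarray               # positions of retained samples
    effect_slices: dict[str, slice]     # coefficient block per fixed effect
    levels: dict[str, list[str]]        # observed levels per factor
    cells: list[tuple[str, ...]]        # factorial cells in level order
    unit_labels: list[str]              # random-unit labels (column order of Z)
    spec: ModelSpec

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class VarianceComponents:
    sigma2_unit: float     # between-unit (pen) variance, >= 0
    sigma2_resid: float    # residual variance, > 0

    @property
    def ratio(self) -> float:
        return self.sigma2_unit / self.sigma2_resid


@dataclass
class MixedFit:
    """REML fit of the mixed model for one metabolite."""

    design: DesignMatrices
    varcomp: VarianceComponents
    beta: np.ndarray
    beta_cov: np.ndarray            # GLS covariance (X' V^-1 X)^-1
    reml_loglik: float
    converged: bool
    n_used: int
    message: str = ""

    @property
    def spec(self) -> ModelSpec:
        return self.design.spec

    def marginal_covariance(self) -> np.ndarray:
        """V = sigma2_unit ZZ' + sigma2_resid I on the retained rows."""
        n = self.design.n
        V = self.varcomp.sigma2_resid * np.eye(n)
        if self.design.Z is not None:
            Z = self.design.Z
            V += self.varcomp.sigma2_unit * (Z @ Z.T)
        return V


def sum_to_zero_codes(n_levels: int) -> np.ndarray:
    """Deviation-coding matrix: row per level, n_levels-1 columns, last level = -1."""
    C = np.eye(n_levels)[:, :-1]
    C[-1, :] = -1.0
    return C


def _observed_levels(values: pd.Series) -> list[str]:
    return sorted(values.astype(str).unique())


def build_design(data: pd.DataFrame, spec: ModelSpec,
                 value_col: str = "value") -> DesignMatrices:
    """Build X, Z and y for one metabolite from its long records.

    Rows with a missing response are deleted casewise before anything else,
    mirroring how PROC MIXED handles missing responses.  The random unit is
    keyed jointly with the treatment cell, so unit labels reused across cells
    are treated as distinct units (nesting).

    Raises
    ------
    DesignError
        If after deletion a factor has fewer than two observed levels, a
        factorial cell is empty, or there are no more units than cells.
    """
    keep = ~data[value_col].isna()
    sub = data.loc[keep]
    row_index = np.flatnonzero(keep.to_numpy())
    n = len(sub)
    factors = [spec.factor1] + ([spec.factor2] if spec.factor2 else [])
    levels = {f: _observed_levels(sub[f]) for f in factors}
    for f in factors:
        if len(levels[f]) < 2:
            raise DesignError(
                f"factor {f!r} has {len(levels[f])} observed level(s) after "
                "deleting missing responses; need at least 2")

    codes = {f: sum_to_zero_codes(len(levels[f])) for f in factors}
    idx = {f: sub[f].astype(str).map(
        {lev: i for i, lev in enumerate(levels[f])}).to_numpy() for f in factors}

    blocks = [np.ones((n, 1))]
    effect_slices: dict[str, slice] = {}
    pos = 1
    for f in factors:
        B = codes[f][idx[f], :]
        blocks.append(B)
        effect_slices[f] = slice(pos, pos + B.shape[1])
        pos += B.shape[1]

    if spec.factor2 is not None:
        cells = [(a, b) for a in levels[spec.factor1] for b in levels[spec.factor2]]
        cell_of = list(zip(sub[spec.factor1].astype(str), sub[spec.factor2].astype(str)))
        counts = pd.Series(cell_of).value_counts()
        empty = [c for c in cells if c not in counts.index]
        if empty:
            raise DesignError(f"empty factorial cell(s) after deletion: {empty}")
        if spec.interaction:
            B1 = codes[spec.factor1][idx[spec.factor1], :]
            B2 = codes[spec.factor2][idx[spec.factor2], :]
            inter = np.einsum("ni,nj->nij", B1, B2).reshape(n, -1)
            blocks.append(inter)
            effect_slices["interaction"] = slice(pos, pos + inter.shape[1])
            pos += inter.shape[1]
    else:
        cells = [(a,) for a in levels[spec.factor1]]
        cell_of = [(a,) for a in sub[spec.factor1].astype(str)]

    X = np.hstack(blocks)

    Z = None
    unit_labels: list[str] = []
    if spec.random_unit is not None:
        unit_key = [cell + (u,) for cell, u in
                    zip(cell_of, sub[spec.random_unit].astype(str))]
        seen: dict[tuple, int] = {}
        col = np.empty(n, dtype=int)
        for i, k in enumerate(unit_key):
            col[i] = seen.setdefault(k, len(seen))
        q = len(seen)
        if q <= len(cells):
            raise DesignError(
                f"only {q} random unit(s) across {len(cells)} cells: the "
                "between-unit variance is confounded with the treatment cells")
        Z = np.zeros((n, q))
        Z[np.arange(n), col] = 1.0
        unit_labels = ["/".join(k) for k in sorted(seen, key=seen.get)]

    return DesignMatrices(X=X, Z=Z, y=sub[value_col].to_numpy(dtype=float),
                          row_index=row_index, effect_slices=effect_slices,
                          levels=levels, cells=cells, unit_labels=unit_labels,
                          spec=spec)


def _profile_pieces(design: DesignMatrices, theta: float):
    """GLS quantities at V0 = I + theta ZZ', with the scale profiled out.

    Returns (beta, A=X'V0^-1 X, quad=y'P0 y, logdetV0, logdetA).
    """
    X, Z, y = design.X, design.Z, design.y
    n = design.n
    if Z is None or theta == 0.0:
        V0inv_X, V0inv_y = X, y
        logdet_V0 = 0.0
    else:
        V0 = np.eye(n) + theta * (Z @ Z.T)
        c, low = linalg.cho_factor(V0, lower=True)
        logdet_V0 = 2.0 * float(np.sum(np.log(np.diag(c))))
        V0inv_X = linalg.cho_solve((c, low), X)
        V0inv_y = linalg.cho_solve((c, low), y)
    A = X.T @ V0inv_X
    try:
        cA = linalg.cho_factor(A)
    except linalg.LinAlgError as exc:
        raise DesignError("fixed-effects design is rank deficient") from exc
    logdet_A = 2.0 * float(np.sum(np.log(np.diag(cA[0]))))
    beta = linalg.cho_solve(cA, X.T @ V0inv_y)
    resid = y - X @ beta
    # y'P0 y equals the GLS weighted residual sum of squares
    if Z is None or theta == 0.0:
        quad = float(resid @ resid)
    else:
        quad = float(resid @ (V0inv_y - V0inv_X @ beta))
    return beta, A, cA, quad, logdet_V0, logdet_A


def _profile_loglik(design: DesignMatrices, theta: float) -> float:
    """REML log-likelihood profiled over sigma2_resid and beta (constants kept)."""
    n, p = design.n, design.p
    _, _, _, quad, logdet_V0, logdet_A = _profile_pieces(design, theta)
    if quad <= 0:
        return np.inf  # degenerate perfect fit
    sigma2 = quad / (n - p)
    return -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1.0)
                   + logdet_V0 + logdet_A)


def fit_reml(design: DesignMatrices) -> MixedFit:
    """Maximize the REML criterion over (sigma2_unit, sigma2_resid).

    With no random term the fit reduces to generalized least squares with
    sigma2_unit = 0 and the usual unbiased residual variance.
    """
    n, p = design.n, design.p
    if n <= p:
        raise DesignError(f"{n} usable samples for {p} fixed-effect "
                          "coefficients: residual variance not estimable")

    if design.Z is None:
        theta_hat = 0.0
        converged = True
        message = "no random term"
    else:
        neg = lambda log_theta: -_profile_loglik(design, float(np.exp(log_theta)))
        res = optimize.minimize_scalar(
            neg, bounds=(np.log(_THETA_MIN), np.log(_THETA_MAX)),
            method="bounded", options={"xatol": _PROFILE_XTOL, "maxiter": 500})
        theta_hat = float(np.exp(res.x))
        ll_boundary = _profile_loglik(design, 0.0)
        ll_interior = -res.fun
        if ll_boundary >= ll_interior or theta_hat <= _THETA_MIN * (1 + 1e-6):
            theta_hat = 0.0
        converged = bool(res.success) or ll_boundary >= ll_interior
        message = "" if converged else str(res.message)

    beta, A, cA, quad, _, _ = _profile_pieces(design, theta_hat)
    sigma2_resid = quad / (n - p)
    varcomp = VarianceComponents(sigma2_unit=theta_hat * sigma2_resid,
                                 sigma2_resid=sigma2_resid)
    beta_cov = sigma2_resid * linalg.cho_solve(cA, np.eye(p))
    beta_cov = 0.5 * (beta_cov + beta_cov.T)
    return MixedFit(design=design, varcomp=varcomp, beta=beta,
                    beta_cov=beta_cov,
                    reml_loglik=_profile_loglik(design, theta_hat),
                    converged=converged, n_used=n, message=message)
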