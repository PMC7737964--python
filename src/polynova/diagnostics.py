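"""Residual normality tests and diagnostic plot data.

Normality is assessed on the marginal residuals y - X beta-hat (observed
minus fixed-effect fitted values, random effects not subtracted), matching
the residuals the original workflow writes out.  Two tests are reported per
metabolite: Shapiro-Wilk and the Lilliefors variant of Kolmogorov-Smirnov
(location and scale estimated from the sample).  Lilliefors p-values above
0.15 are reported as the conventional cap 0.15; the raw value is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

from .errors import ExportError
from .inference import KRAdjustment  # noqa: F401  (re-exported context type)
from .mixed_model import MixedFit

__all__ = ["NormalityResult", "marginal_residuals", "shapiro_wilk",
           "ks_normality", "plot_data", "KS_REPORT_CAP"]

#: Lilliefors p-values above this are reported as the cap itself
KS_REPORT_CAP = 0.15


@dataclass
class NormalityResult:
    shapiro_w: float
    shapiro_p: float
    ks_d: float
    ks_p: float            # raw Lilliefors p
    ks_p_reported: float   # min(ks_p, 0.15) per the reporting convention
    n_residuals: int


def marginal_residuals(fit: MixedFit) -> np.ndarray:
    """Marginal residuals r = y - X beta-hat on the analysis scale."""
    return fit.design.y - fit.design.X @ fit.beta


def shapiro_wilk(residuals) -> tuple[float, float]:
    """Shapiro-Wilk W and p; returns (nan, nan) for fewer than 3 residuals."""
    r = np.asarray(residuals, dtype=float)
    r = r[~np.isnan(r)]
    if r.size < 3:
        return float("nan"), float("nan")
    W, p = stats.shapiro(r)
    return float(W), float(p)


def ks_normality(residuals) -> tuple[float, float]:
    """Lilliefors D and raw p; returns (nan, nan) for fewer than 5 residuals."""
    r = np.asarray(residuals, dtype=float)
    r = r[~np.isnan(r)]
    if r.size < 5:
        return float("nan"), float("nan")
    D, p = _lilliefors(r, dist="norm", pvalmethod="table")
    return float(D), float(p)


def normality_tests(fit: MixedFit) -> NormalityResult:
    """Run both residual normality tests for one fitted metabolite."""
    r = marginal_residuals(fit)
    W, sw_p = shapiro_wilk(r)
    D, ks_p = ks_normality(r)
    reported = min(ks_p, KS_REPORT_CAP) if np.isfinite(ks_p) else ks_p
    return NormalityResult(shapiro_w=W, shapiro_p=sw_p, ks_d=D, ks_p=ks_p,
                           ks_p_reported=reported, n_residuals=int(r.size))


def qq_pairs(residuals) -> pd.DataFrame:
    """Normal QQ data with Blom plotting positions (i - 3/8)/(n + 1/4)."""
    r = np.sort(np.asarray(residuals, dtype=float))
    n = r.size
    probs = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    return pd.DataFrame({"theoretical_quantile": stats.norm.ppf(probs),
                         "ordered_residual": r})


def plot_data(fit: MixedFit, name: str, normgraphpath=None, fitgraphpath=None,
              render: bool = False) -> dict[str, pd.DataFrame]:
    """QQ and fitted-vs-residual plot data; optionally written and rendered.

    Returns the two data frames keyed "qq" and "fit"; when paths are given,
    one CSV per metabolite is written there (and a PNG when render=True).
    """
    r = marginal_residuals(fit)
    qq = qq_pairs(r)
    fitted = fit.design.X @ fit.beta
    fv = pd.DataFrame({"fitted": fitted, "residual": r})
    out = {"qq": qq, "fit": fv}
    for frame, path, kind in ((qq, normgraphpath, "qq"),
                              (fv, fitgraphpath, "fitted_vs_residuals")):
        if path is None:
            continue
        path = Path(path)
        try:
            path.mkdir(parents=True, exist_ok=True)
            frame.to_csv(path / f"{name}_{kind}.csv", index=False)
        except OSError as exc:
            raise ExportError(f"cannot write plot data under {path}: {exc}") from exc
        if render:
            _render(frame, kind, path / f"{name}_{kind}.png")
    return out


def _render(frame: pd.DataFrame, kind: str, target: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    x, y = frame.columns[:2]
    ax.scatter(frame[x], frame[y], s=12)
    if kind == "qq":
        lims = [frame.min().min(), frame.max().max()]
        ax.plot(lims, lims, lw=1, color="grey")
    else:
        ax.axhline(0.0, lw=1, color="grey")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    fig.tight_layout()
    fig.savefig(target, dpi=100)
    plt.close(fig)
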