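"""Across-metabolite p-value adjustment, one family per fixed effect.

With hundreds of metabolites tested one at a time, raw ANOVA p-values are
adjusted for the number of metabolites by the Benjamini-Hochberg step-up
(FDR) procedure or Bonferroni.  Each effect (first treatment, second
treatment, interaction) forms its own family across metabolites, matching
the adjacent raw/adjusted column pairs of the consolidated output.  Missing
p-values (metabolites whose fit failed) stay missing and do not count toward
the family size, the behaviour of PROC MULTTEST.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import PolynovaError

__all__ = ["adjust_bh", "adjust_bonferroni", "adjust_all_effects"]


def _checked(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    ok = np.isnan(p) | ((p >= 0.0) & (p <= 1.0))
    if not ok.all():
        bad = p[~ok][0]
        raise PolynovaError(f"p-value out of [0, 1]: {bad!r}")
    return p


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Non-missing values are ranked ascending; q_(i) = min over j >= i of
    m * p_(j) / j, clipped at 1, with m the number of non-missing p-values;
    missing entries pass through as NaN.
    """
    p = _checked(pvals)
    out = np.full_like(p, np.nan)
    idx = np.flatnonzero(~np.isnan(p))
    m = idx.size
    if m == 0:
        return out
    order = idx[np.argsort(p[idx], kind="stable")]
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out[order] = np.minimum(q, 1.0)
    return out


def adjust_bonferroni(pvals) -> np.ndarray:
    """Bonferroni: min(1, m * p) with m = number of non-missing p-values."""
    p = _checked(pvals)
    m = int(np.sum(~np.isnan(p)))
    return np.minimum(p * m, 1.0)


_METHODS = {"fdr": adjust_bh, "bh": adjust_bh, "bonferroni": adjust_bonferroni}


def adjust_all_effects(tests: pd.DataFrame, method: str = "fdr") -> pd.DataFrame:
    """Adjust a metabolite x effect table of raw p-values, per effect family.

    ``tests`` has one row per metabolite and one column per effect; the
    return has the same shape and index with adjusted values.
    """
    try:
        fn = _METHODS[method.lower()]
    except KeyError:
        raise PolynovaError(f"unknown feature adjustment {method!r}; "
                            "use 'fdr' or 'bonferroni'") from None
    return tests.apply(lambda col: pd.Series(fn(col.to_numpy()), index=col.index))
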