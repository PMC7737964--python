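"""Normality transformations applied to peak intensities before modelling.

Three codes are supported, mirroring the ``normtrans`` switch of the original
workflow: 0 = no transformation, 1 = natural logarithm (the default for
positively skewed peak-area data), 2 = square root.  Estimates computed on the
transformed scale are mapped back to the measurement scale for reporting with
the exact inverse, which preserves the ordering of point estimates and
interval endpoints because both maps are strictly monotone on their domains.
"""

from __future__ import annotations

import enum

import numpy as np

from .errors import TransformDomainError

__all__ = ["TransformCode", "apply_transform", "back_transform_point_and_interval"]


class TransformCode(enum.IntEnum):
    """Response transformation: identity, natural log, or square root."""

    NONE = 0
    LOG = 1
    SQRT = 2

    @property
    def label(self) -> str:
        """Human-readable label used in the ``Transformation`` output column."""
        return {TransformCode.NONE: "none",
                TransformCode.LOG: "log",
                TransformCode.SQRT: "sqrt"}[self]


def _as_code(code: "TransformCode | int") -> TransformCode:
    try:
        return TransformCode(code)
    except ValueError as exc:
        raise ValueError(f"unknown transformation code {code!r}; "
                         "valid codes are 0 (none), 1 (log), 2 (sqrt)") from exc


def apply_transform(values, code, *, name: str = "response") -> np.ndarray:
    """Transform a response vector elementwise; NaN (missing) stays NaN.

    Parameters
    ----------
    values : array-like of float
        Raw intensities; missing values encoded as NaN.
    code : TransformCode or int
        0 identity, 1 natural log (requires positive values), 2 square root
        (requires nonnegative values).
    name : str
        Metabolite name used in error messages.

    Raises
    ------
    TransformDomainError
        If a non-missing value lies outside the transform's domain; the
        message identifies the metabolite and the offending sample position.
    """
    code = _as_code(code)
    x = np.asarray(values, dtype=float)
    if code is TransformCode.NONE:
        return x.copy()
    finite = ~np.isnan(x)
    if code is TransformCode.LOG:
        bad = finite & (x <= 0)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise TransformDomainError(
                f"log transform of {name!r}: nonpositive value {x[i]!r} "
                f"at sample index {i}")
        out = np.full_like(x, np.nan)
        out[finite] = np.log(x[finite])
        return out
    bad = finite & (x < 0)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise TransformDomainError(
            f"sqrt transform of {name!r}: negative value {x[i]!r} "
            f"at sample index {i}")
    out = np.full_like(x, np.nan)
    out[finite] = np.sqrt(x[finite])
    return out


def back_transform_point_and_interval(estimate: float, lower: float,
                                      upper: float, code) -> tuple[float, float, float]:
    """Map (estimate, lower, upper) from the analysis scale back to the data scale.

    The identity map leaves the triple unchanged; the log map exponentiates;
    the square-root map squares (requiring all three nonnegative, otherwise
    the squared interval would not be an interval for the mean response).
    NaN components pass through unchanged.
    """
    code = _as_code(code)
    trio = np.array([estimate, lower, upper], dtype=float)
    finite = ~np.isnan(trio)
    if finite.sum() == 3 and not (lower <= estimate <= upper):
        raise TransformDomainError(
            f"interval ordering violated: lower={lower}, estimate={estimate}, "
            f"upper={upper}")
    if code is TransformCode.NONE:
        out = trio
    elif code is TransformCode.LOG:
        out = np.exp(trio)
    else:
        if (trio[finite] < 0).any():
            raise TransformDomainError(
                "sqrt back-transform requires nonnegative estimate and interval "
                f"endpoints, got {tuple(trio)}")
        out = np.square(trio)
    return float(out[0]), float(out[1]), float(out[2])
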