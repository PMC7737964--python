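"""Reading, validating and reshaping wide-format feature tables, and writing results.

The expected input is a comma-separated file with one row per sample and one
column per metabolite, plus columns naming the sample and the design factors
(two crossed treatments and the housing unit nested within their cells).
Missing intensities are encoded as ``.`` (canonical) or an empty cell.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ExportError, InputError, MissingColumnError, ResponseParseError

__all__ = [
    "FeatureTable",
    "ValidationReport",
    "read_wide_table",
    "validate_names",
    "to_long",
    "export_results",
]

MISSING_TOKENS = (".", "")

#: component files written when ``singlefile=False`` (one per result block)
RESULT_COMPONENTS = ("normality", "anova", "lsmeans", "pairwise_raw", "pairwise_adjusted")


@dataclass
class FeatureTable:
    """A wide sample-by-metabolite table with the design factors split out.

    Attributes
    ----------
    sample_id : pd.Series
        Text identifier per row (first column of the input by convention).
    factors : pd.DataFrame
        One column per design variable (treatments plus excluded variables
        such as the animal and pen identifiers), aligned with ``responses``.
    responses : pd.DataFrame
        Float matrix of intensities, NaN where the input held a missing code.
    """

    sample_id: pd.Series
    factors: pd.DataFrame
    responses: pd.DataFrame

    @property
    def metabolite_names(self) -> list[str]:
        return list(self.responses.columns)

    @property
    def n_samples(self) -> int:
        return len(self.responses)

    def __post_init__(self) -> None:
        if self.responses.shape[1] == 0:
            raise InputError("feature table has no response (metabolite) columns")
        names = self.metabolite_names
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InputError(f"duplicate metabolite columns: {dupes}")
        overlap = set(self.factors.columns) & set(names)
        if overlap:
            raise InputError(f"columns used both as factor and response: {sorted(overlap)}")


@dataclass
class ValidationReport:
    """Outcome of the variable-name check; collects violations, never raises."""

    violations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not self.violations


_NAME_OK = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def validate_names(names) -> ValidationReport:
    """Check variable names for portability with the original SAS workflow.

    Flags names of 32 characters or more, names containing characters other
    than letters, digits and underscores, and names starting with a digit.
    """
    report = ValidationReport()
    for name in names:
        if len(name) >= 32:
            report.violations.append((name, "length >= 32 characters"))
        if not _NAME_OK.match(name):
            if name and name[0].isdigit():
                report.violations.append((name, "starts with a digit"))
            bad = sorted({c for c in name if not (c.isalnum() or c == "_")})
            if bad:
                report.violations.append(
                    (name, "special characters: " + "".join(bad)))
    return report


def _parse_response_column(col: pd.Series, name: str) -> pd.Series:
    """Parse one response column to float, accepting the missing tokens."""
    as_str = col.astype("string").str.strip()
    missing = as_str.isna() | as_str.isin(MISSING_TOKENS)
    out = pd.to_numeric(as_str.where(~missing), errors="coerce")
    bad = out.isna() & ~missing
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ResponseParseError(
            f"non-numeric value {col.iloc[row]!r} in response column {name!r} "
            f"at data row {row}")
    return out.astype(float)


def read_wide_table(path, treatment_var1: str, treatment_var2: str | None = None,
                    exclude_vars=(), ignore_vars=(),
                    sample_id_var: str | None = None) -> FeatureTable:
    """Read a wide CSV into a :class:`FeatureTable`.

    Every column not named as a treatment, excluded variable or ignored
    variable is taken to be a metabolite response.  Excluded variables are
    kept as factors (available to the model, e.g. the pen identifier);
    ignored variables are dropped entirely.

    Parameters
    ----------
    path : path-like
        CSV file with a header row.
    treatment_var1, treatment_var2 : str
        The crossed treatment columns; ``treatment_var2`` is None for the
        one-way analysis.
    exclude_vars, ignore_vars : iterable of str
        Non-response columns to retain as factors / to drop.
    sample_id_var : str, optional
        Column holding the sample identifier; defaults to the first excluded
        variable if any, otherwise the row number.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [str(c).strip() for c in raw.columns]

    exclude_vars = list(exclude_vars)
    ignore_vars = list(ignore_vars)
    treatments = [treatment_var1] + ([treatment_var2] if treatment_var2 else [])
    declared = treatments + exclude_vars + ignore_vars
    missing_cols = [c for c in declared if c not in raw.columns]
    if missing_cols:
        raise MissingColumnError(
            f"declared columns not in header: {missing_cols}; "
            f"header is {list(raw.columns)}")

    factor_cols = [c for c in treatments + exclude_vars
                   if c not in ignore_vars]
    response_cols = [c for c in raw.columns if c not in set(declared)]
    if not response_cols:
        raise InputError("no response columns remain after removing "
                         "treatment/exclude/ignore columns")

    responses = pd.DataFrame(
        {c: _parse_response_column(raw[c], c) for c in response_cols})
    factors = raw[factor_cols].copy()
    if sample_id_var is None:
        sample_id_var = exclude_vars[0] if exclude_vars else None
    if sample_id_var is not None and sample_id_var in raw.columns:
        sample_id = raw[sample_id_var].copy()
    else:
        sample_id = pd.Series([str(i) for i in range(len(raw))], name="sample")
    return FeatureTable(sample_id=sample_id, factors=factors, responses=responses)


def to_long(table: FeatureTable) -> pd.DataFrame:
    """Reshape to long form: one record per (metabolite, sample).

    Records are grouped by metabolite (in input column order) and keep the
    input sample order within each group, so downstream per-metabolite fits
    can stream group by group.  Missing responses stay NaN.
    """
    n = table.n_samples
    base = table.factors.copy()
    base.insert(0, "sample_id", table.sample_id.to_numpy())
    frames = []
    for name in table.metabolite_names:
        block = base.copy()
        block["response_name"] = name
        block["value"] = table.responses[name].to_numpy()
        frames.append(block)
    long = pd.concat(frames, ignore_index=True)
    assert len(long) == n * len(table.metabolite_names)
    return long


def from_long(long: pd.DataFrame, table: FeatureTable) -> pd.DataFrame:
    """Regroup a long table back to the wide responses matrix (round-trip check)."""
    wide = long.pivot_table(index="sample_id", columns="response_name",
                            values="value", dropna=False, aggfunc="first",
                            sort=False)
    wide = wide.reindex(index=table.sample_id.to_numpy(),
                        columns=table.metabolite_names)
    return wide.reset_index(drop=True)


def _sorted_rows(rows: pd.DataFrame, sort_by: str | None) -> pd.DataFrame:
    """Stable ascending sort by the first treatment's raw ANOVA p; NaN last."""
    if sort_by is None or sort_by not in rows.columns:
        return rows
    return rows.sort_values(sort_by, kind="stable", na_position="last")


def export_results(rows: pd.DataFrame, name: str, singlefile: bool,
                   respath, sort_by: str | None = None,
                   component_columns: dict[str, list[str]] | None = None) -> list[Path]:
    """Write the consolidated results, as one CSV or one CSV per component.

    Rows are sorted ascending by ``sort_by`` (the first treatment variable's
    raw ANOVA p-value), failed fits (NaN) last, ties in input order.  Missing
    values are written as ``.``.  Returns the list of files written.
    """
    if rows.empty:
        raise ExportError("no result rows to export")
    if " " in name:
        name = name.replace(" ", "_")
    respath = Path(respath)
    try:
        respath.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ExportError(f"cannot create results directory {respath}: {exc}") from exc

    out = _sorted_rows(rows, sort_by)
    written: list[Path] = []

    def _write(frame: pd.DataFrame, stem: str) -> None:
        target = respath / f"{stem}.csv"
        try:
            frame.to_csv(target, index=False, na_rep=".")
        except OSError as exc:
            raise ExportError(f"cannot write {target}: {exc}") from exc
        written.append(target)

    if singlefile:
        _write(out, name)
    else:
        id_cols = [c for c in ("Response", "Transformation", "status")
                   if c in out.columns]
        groups = component_columns or _default_components(out.columns)
        for component in RESULT_COMPONENTS:
            cols = [c for c in groups.get(component, []) if c in out.columns]
            _write(out[id_cols + cols], f"{name}_{component}")
    return written


def _default_components(columns) -> dict[str, list[str]]:
    """Partition consolidated columns into the five result components."""
    cols = list(columns)
    groups: dict[str, list[str]] = {c: [] for c in RESULT_COMPONENTS}
    for c in cols:
        if c in ("Shapiro_Wilk", "Kolmogorov"):
            groups["normality"].append(c)
        elif c.startswith(("Pvalue_", "AdjPvalue_")):
            groups["anova"].append(c)
        elif c.startswith(("LS_", "CI_Lower_", "CI_Upper_")):
            groups["lsmeans"].append(c)
        elif c.startswith("P_valueD"):
            groups["pairwise_raw"].append(c)
        elif c.startswith(("TukeyD", "BonfD")):
            groups["pairwise_adjusted"].append(c)
    return groups
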