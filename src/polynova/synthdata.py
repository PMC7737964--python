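"""Synthetic feature tables with the exact structure the mixed model assumes.

The generator emulates a 2x2 factorial animal study with pens nested in the
treatment cells and a small number of animals per pen: log-intensities are

    log y = mu_m + alpha + gamma + (alpha gamma) + pen + error

with pen ~ N(0, sigma2_pen) and error ~ N(0, sigma2_resid), exponentiated to
positive peak areas (so the log transform is the correct analysis scale).
Defaults reproduce the structure of the motivating liver study: two levels
per factor, 4/3/4/3 pens per cell housing pairs of animals, 26 retained
samples (8/5/8/5 per cell), 218 metabolites, and a sprinkle of missing
values written as ".".  Effect sizes are zero unless requested, giving a
global-null table for calibration tests.

Metabolites are generated independently, as the one-at-a-time model assumes;
real co-regulation between metabolites is deliberately not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .io import FeatureTable

__all__ = ["SimDesign", "SimTruth", "simulate", "write_wide_csv"]

#: pens per factorial cell, in (factor1, factor2) level order, as in the
#: motivating study: (N,CON)=4, (N,HFF)=3, (P,CON)=4, (P,HFF)=3
PAPER_PENS_PER_CELL = (4, 3, 4, 3)
#: animals dropped (cell_index, pen_within_cell) to reach the 8/5/8/5 samples
PAPER_DROPS = ((1, 2), (3, 2))


@dataclass
class SimDesign:
    """Parameters of one synthetic study.

    Variances are on the log-intensity scale; ``effect_factor1`` etc. are
    half-differences between the two levels of each factor (a level-coded
    effect of +e gives a 2e log-fold difference between levels).
    """

    seed: int
    levels_factor1: tuple[str, ...] = ("N", "P")
    levels_factor2: tuple[str, ...] | None = ("CON", "HFF")
    pens_per_cell: tuple[int, ...] = PAPER_PENS_PER_CELL
    animals_per_pen: int = 2
    drop_animals: tuple[tuple[int, int], ...] = PAPER_DROPS
    n_metabolites: int = 218
    baseline_mean: float = 8.0      # mean log peak area across metabolites
    baseline_sd: float = 2.0        # spread of baselines across metabolites
    effect_factor1: float = 0.0
    effect_factor2: float = 0.0
    effect_interaction: float = 0.0
    sigma2_pen: float = 0.1
    sigma2_resid: float = 0.25
    missing_rate: float = 0.005
    factor1: str = "Trx1"
    factor2: str | None = "Trx2"
    unit: str = "pen"

    def __post_init__(self) -> None:
        if self.sigma2_pen < 0 or self.sigma2_resid <= 0:
            raise InputError("variances must be nonnegative (residual positive)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InputError("missing_rate must be in [0, 1)")
        n_cells = len(self.cells)
        if len(self.pens_per_cell) != n_cells:
            raise InputError(f"pens_per_cell needs {n_cells} entries")

    @property
    def cells(self) -> list[tuple[str, ...]]:
        if self.levels_factor2 is None or self.factor2 is None:
            return [(a,) for a in self.levels_factor1]
        return [(a, b) for a in self.levels_factor1 for b in self.levels_factor2]


@dataclass
class SimTruth:
    """Everything needed for parameter-recovery tests."""

    design: SimDesign
    baselines: np.ndarray                 # per-metabolite mu_m
    cell_shift: dict[tuple[str, ...], float]   # fixed-effect log shift per cell
    pen_effects: pd.DataFrame = field(repr=False, default=None)


def _cell_shift(design: SimDesign, cell: tuple[str, ...]) -> float:
    """Sum-to-zero fixed-effect contribution of one cell, on the log scale."""
    s1 = 1.0 if cell[0] == design.levels_factor1[0] else -1.0
    shift = design.effect_factor1 * s1
    if design.factor2 is not None and len(cell) > 1:
        s2 = 1.0 if cell[1] == design.levels_factor2[0] else -1.0
        shift += design.effect_factor2 * s2 + design.effect_interaction * s1 * s2
    return shift


def simulate(design: SimDesign) -> tuple[FeatureTable, SimTruth]:
    """Draw one synthetic wide table plus its generating truth record."""
    rng = np.random.default_rng(design.seed)
    rows = []
    pen_counter = 0
    drops = set(design.drop_animals)
    for ci, cell in enumerate(design.cells):
        for pj in range(design.pens_per_cell[ci]):
            pen_counter += 1
            n_animals = design.animals_per_pen - (1 if (ci, pj) in drops else 0)
            for _ in range(n_animals):
                row = {"pig": f"pig{len(rows) + 1:02d}",
                       design.unit: f"pen{pen_counter:02d}",
                       design.factor1: cell[0]}
                if design.factor2 is not None:
                    row[design.factor2] = cell[1]
                row["_cell"] = ci
                rows.append(row)
    frame = pd.DataFrame(rows)
    n = len(frame)
    m = design.n_metabolites

    baselines = rng.normal(design.baseline_mean, design.baseline_sd, size=m)
    shifts = np.array([_cell_shift(design, design.cells[ci])
                       for ci in frame["_cell"]])
    pen_codes, pen_labels = pd.factorize(frame[design.unit])
    pen_fx = rng.normal(0.0, np.sqrt(design.sigma2_pen),
                        size=(len(pen_labels), m))
    noise = rng.normal(0.0, np.sqrt(design.sigma2_resid), size=(n, m))
    log_y = baselines[None, :] + shifts[:, None] + pen_fx[pen_codes, :] + noise
    values = np.exp(log_y)
    if design.missing_rate > 0:
        values[rng.random(size=values.shape) < design.missing_rate] = np.nan

    met_names = [f"met{j + 1:03d}" for j in range(m)]
    responses = pd.DataFrame(values, columns=met_names)
    factors = frame.drop(columns=["_cell"])
    table = FeatureTable(sample_id=factors["pig"].copy(),
                         factors=factors, responses=responses)
    truth = SimTruth(design=design, baselines=baselines,
                     cell_shift={c: _cell_shift(design, c) for c in design.cells},
                     pen_effects=pd.DataFrame(pen_fx, index=list(pen_labels),
                                              columns=met_names))
    return table, truth


def write_wide_csv(table: FeatureTable, path) -> Path:
    """Write a FeatureTable in the wide CSV dialect the reader accepts,
    with missing responses encoded as "."."""
    path = Path(path)
    wide = pd.concat([table.factors.reset_index(drop=True),
                      table.responses.reset_index(drop=True)], axis=1)
    path.parent.mkdir(parents=True, exist_ok=True)
    wide.to_csv(path, index=False, na_rep=".")
    return path
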