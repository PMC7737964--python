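import numpy as np
import pandas as pd
import pytest

from polynova import ModelSpec, SimDesign, TransformCode, simulate
from polynova.inference import kenward_roger, type3_test
from polynova.mixed_model import build_design, fit_reml


def long_one(table, name="met001"):
    """Long records for one metabolite of a FeatureTable."""
    df = table.factors.copy()
    df["value"] = table.responses[name].to_numpy()
    return df


@pytest.fixture(scope="session")
def oracle_table():
    """The fixture cross-checked against lme4/pbkrtest/emmeans: one
    metabolite on the 26-sample 2x2 pens-in-cells design, a diet effect of
    0.4 on the log scale, no missing values."""
    design = SimDesign(seed=42, n_metabolites=1, effect_factor2=0.4,
                       missing_rate=0.0)
    table, truth = simulate(design)
    return table, truth


@pytest.fixture(scope="session")
def oracle_fit(oracle_table):
    """REML fit + KR adjustment of the oracle metabolite on the log scale."""
    table, _ = oracle_table
    df = long_one(table)
    df["value"] = np.log(df["value"])
    spec = ModelSpec(factor1="Trx1", factor2="Trx2", random_unit="pen",
                     transform=TransformCode.NONE)
    fit = fit_reml(build_design(df, spec))
    return fit, kenward_roger(fit)


def balanced_table(seed=7, pens_per_cell=3, animals=2, m=1, **kw):
    """A fully balanced 2x2 design (equal pens per cell, no drops)."""
    design = SimDesign(seed=seed, n_metabolites=m,
                       pens_per_cell=(pens_per_cell,) * 4,
                       animals_per_pen=animals, drop_animals=(),
                       missing_rate=0.0, **kw)
    return simulate(design)


@pytest.fixture(scope="session")
def null_sim():
    """Global-null simulation shared by the calibration tests: 30 replicate
    studies of 100 metabolites each on the 26-sample design, zero effects.
    Returns raw Type III p-values per effect (pooled) and the per-replicate
    BH false-discovery proportion at q = 0.05."""
    from polynova.multitest import adjust_bh

    reps, m = 30, 100
    spec = ModelSpec(factor1="Trx1", factor2="Trx2", random_unit="pen",
                     transform=TransformCode.NONE)
    pooled = {e: [] for e in ("Trx1", "Trx2", "interaction")}
    fdp = []
    for rep in range(reps):
        design = SimDesign(seed=10_000 + rep, n_metabolites=m, missing_rate=0.0)
        table, _ = simulate(design)
        base = table.factors
        per_effect = {e: np.empty(m) for e in pooled}
        for j, name in enumerate(table.metabolite_names):
            df = base.copy()
            df["value"] = np.log(table.responses[name].to_numpy())
            fit = fit_reml(build_design(df, spec))
            kr = kenward_roger(fit)
            for e in per_effect:
                per_effect[e][j] = type3_test(fit, kr, e).p_raw
        for e in pooled:
            pooled[e].append(per_effect[e])
            # every rejection under the global null is false, so the
            # false-discovery proportion of this family is 1{R > 0}
            rejected = int(np.sum(adjust_bh(per_effect[e]) <= 0.05))
            fdp.append(1.0 if rejected > 0 else 0.0)
    return ({e: np.concatenate(v) for e, v in pooled.items()}, np.array(fdp))
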