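import numpy as np
import pandas as pd
import pytest

from dietmwas import MetabolitePanel, PlantedEffect, SimParams, simulate_cohort


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    return SimParams(
        n_pairs=60,
        frac_mz=0.5,
        n_food_groups=4,
        n_metabolites_nt=5,
        n_metabolites_t=3,
        n_run_days=3,
        n_snps=4,
        missing_rate=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return simulate_cohort(small_params)


@pytest.fixture(scope="session")
def planted_cohort():
    """200 pairs with one strong non-targeted effect and one targeted effect."""
    params = SimParams(
        n_pairs=200,
        frac_mz=0.5,
        n_food_groups=3,
        n_metabolites_nt=4,
        n_metabolites_t=2,
        n_run_days=4,
        n_snps=0,
        missing_rate=0.0,
        batch_shift_sd=0.0,
        effect_table=(
            PlantedEffect(0, 1, "non_targeted", 0.08),
            PlantedEffect(2, 0, "targeted", 0.08),
        ),
        seed=7,
    )
    return simulate_cohort(params)


def make_panel(values, platform="non_targeted", run_day=None, steps=()):
    """Hand-built panel from a plain array: subjects S0, S1, ... ."""
    values = np.asarray(values, dtype=float)
    idx = pd.Index([f"S{i}" for i in range(values.shape[0])], name="subject_id")
    cols = [f"m{j}" for j in range(values.shape[1])]
    rd = None
    if run_day is not None:
        rd = pd.Series(list(run_day), index=idx, name="run_day")
    return MetabolitePanel(
        values=pd.DataFrame(values, index=idx, columns=cols),
        platform=platform,
        run_day=rd,
        steps=list(steps),
    )
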