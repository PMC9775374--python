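import numpy as np
import pytest

from serumftir import CohortConfig, default_band_table, generate_cohort


@pytest.fixture(scope="session")
def band_table():
    return default_band_table()


@pytest.fixture(scope="session")
def default_cohort():
    """The full 252-sample study-sized cohort (seed 42)."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture()
def noiseless_config():
    return CohortConfig(noise_sigma=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def small_cohort_config(seed=0, noise=0.002, stage_scales=None, n_per_group=12):
    """Reduced cohort for fast classification tests."""
    kw = {}
    if stage_scales is not None:
        kw["stage_scales"] = stage_scales
    return CohortConfig(
        group_sizes={"LC": n_per_group, "GC": n_per_group, "CC": n_per_group,
                     "Control": n_per_group},
        second_specimens={"LC": 0, "GC": 0, "CC": 0},
        noise_sigma=noise,
        seed=seed,
        **kw,
    )
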