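import warnings

import pytest

from gcregulome.pipeline import run_all
from gcregulome.synthetic_data import SimConfig, simulate_study


def small_config(seed: int = 1, **overrides) -> SimConfig:
    """Desk-scale study conditions shared by cross-module tests."""
    kwargs = dict(
        seed=seed,
        n_regions=300,
        n_genes=60,
        n_patients=40,
        n_variants=20,
        depth_mean=2e5,
        cohort_depth=1e5,
        n_loops=120,
        n_planted_loops=15,
        footprint_sites_per_tf=60,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def study():
    """One small synthetic study reused across module tests."""
    return simulate_study(small_config(seed=1))


@pytest.fixture(scope="session")
def full_run():
    """One end-to-end pipeline run on the small study."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_all(small_config(seed=1), outdir=None, write_outputs=False)
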