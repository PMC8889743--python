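import pytest
from hypothesis import HealthCheck, settings

from circsig import SimConfig, simulate_cohort
from circsig.synthetic_data import write_fixture

settings.register_profile(
    "fixed",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def cohort():
    """Full-size simulated cohort: 7 tissues x 10 patients, paired."""
    return simulate_cohort(SimConfig(rng_seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort for I/O and CLI round-trips (< 1 s to build and write)."""
    return simulate_cohort(
        SimConfig(rng_seed=11, n_genes=80, patients_per_tissue=3)
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_cohort):
    out = tmp_path_factory.mktemp("cohort") / "fix"
    write_fixture(out, small_cohort)
    return out
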