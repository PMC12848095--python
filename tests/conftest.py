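import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def two_clone_fixture():
    from alfak.io import generate_fixture

    return generate_fixture("two_clone", seed=3)


@pytest.fixture(scope="session")
def smooth_fixture():
    from alfak.io import generate_fixture

    return generate_fixture("smooth_grf", seed=11)


@pytest.fixture(scope="session")
def smooth_fit(smooth_fixture):
    """One full landscape fit on the smooth-GRF fixture, shared by tests."""
    from alfak.inference import InferenceConfig, fit_landscape

    n_cells = smooth_fixture.counts.totals.sum()
    cfg = InferenceConfig(
        min_obs=max(10, int(round(0.01 * n_cells))),
        p=smooth_fixture.manifest["sim"]["p"],
    )
    return fit_landscape(smooth_fixture.counts, cfg)
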