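import pytest

from foamimpact import FoamParams, StudyConfig, run_full_study


@pytest.fixture(scope="session")
def config() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def default_params() -> FoamParams:
    return FoamParams()


@pytest.fixture(scope="session")
def noise_free_params() -> FoamParams:
    return FoamParams(noise_force_sd=0.0, noise_disp_sd=0.0, specimen_cv=0.0)


@pytest.fixture(scope="session")
def study():
    """Full seeded synthetic study with the factory-calibrated foam."""
    manifest, results = run_full_study(seed=1)
    return manifest, results
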