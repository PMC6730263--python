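import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from isoflux import TruthBundle, generate_season  # noqa: E402


def zero_noise_bundle(**kwargs) -> TruthBundle:
    base = dict(
        seed=7,
        noise_sd_flux_co2=0.0,
        noise_sd_flux_h2o=0.0,
        noise_sd_delta=0.0,
        ec_noise_sd_nee=0.0,
        ec_noise_sd_et=0.0,
        ec_offset_nee=0.0,
        ec_offset_et=0.0,
    )
    base.update(kwargs)
    return TruthBundle(**base)


@pytest.fixture(scope="session")
def quiet_season():
    """A noise-free synthetic season shared across tests."""
    return generate_season(zero_noise_bundle())


@pytest.fixture(scope="session")
def default_season():
    """A season with the default (noisy) measurement layer."""
    return generate_season(TruthBundle(seed=7))
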