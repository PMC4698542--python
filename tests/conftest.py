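import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def zero_noise_design():
    """Default effects but no animal, batch, or loading noise anywhere."""
    from blotkit import default_design
    from blotkit.synthetic import DEFAULT_GROUPS, DEFAULT_PROTEINS, LOADING_CONTROL

    proteins = DEFAULT_PROTEINS + (LOADING_CONTROL,)
    noise = {(g, p): 0.0 for g, _ in DEFAULT_GROUPS for p in proteins}
    return default_design(batch_sd=0.0, loading_sd=0.0, noise_sd=noise)


@pytest.fixture(scope="session")
def default_bundle():
    """One default-design synthetic study, shared across tests."""
    from blotkit import default_design, generate_table

    return generate_table(default_design(), seed=11)


@pytest.fixture(scope="session")
def zero_noise_bundle():
    """Noise-free synthetic study: every raw density equals its design truth."""
    from blotkit import generate_table

    return generate_table(zero_noise_design(), seed=5)
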