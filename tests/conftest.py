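import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def trial():
    """The bundled gibel carp trial tables."""
    from aquatrial import load_gibel_trial

    return load_gibel_trial()
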