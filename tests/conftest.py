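import pytest

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "default",
        derandomize=True,
        max_examples=50,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("default")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture
def resting_cell_endpoints():
    """Washed-cell glucose fermentation endpoints (mM) in bicarbonate buffer."""
    consumed = {"glucose": 12.15}
    formed = {
        "acetate": 13.62,
        "succinate": 10.12,
        "formate": 5.23,
        "lactate": 0.36,
        "H2": 5.05,
    }
    return consumed, formed
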