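import pytest
from hypothesis import HealthCheck, settings

from pyrocall import builtin_assays
from pyrocall.io_synth import SynthConfig, synth_pyrogram

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=75,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def assays():
    """Built-in assays keyed by name."""
    return {a.name: a for a in builtin_assays()}


@pytest.fixture(scope="session")
def noiseless():
    """Factory for exact (noise-free) synthetic pyrograms at scale 100."""

    def make(assay_name, variant=None, fraction=0.0, scale=100.0):
        return synth_pyrogram(
            SynthConfig(
                assay=assay_name,
                variant=variant,
                fraction=fraction,
                scale=scale,
                noise_sd=0.0,
                nonspecific_range=(0.0, 0.0),
                seed=0,
            )
        )

    return make
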