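import pytest
from hypothesis import HealthCheck, settings

import mammocea as m

settings.register_profile(
    "default",
    derandomize=True,
    database=None,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundle():
    """The frozen reference scenario."""
    return m.reference_bundle()


@pytest.fixture(scope="session")
def evals(bundle):
    """Trace + economics for every strategy at the default 40% compliance."""
    return m.evaluate_all(bundle)


@pytest.fixture(scope="session")
def zero_bundle():
    """A cancer-free, immortal world: every hazard zero."""
    spec = m.SyntheticBundleSpec(
        onset_scale=0.0,
        clinical_detection_base=0.0,
        bc_mortality_base=0.0,
        bc_mortality_recurrence=0.0,
        recurrence_base=0.0,
        other_mortality_at_50=0.0,
    )
    return m.generate_bundle(spec)
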