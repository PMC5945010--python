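import numpy as np
import pytest

from ambientgreen import synth


def small_profile(
    name: str = "Testpark",
    base: float = 0.32,
    amplitude: float = 0.04,
    counts: int = 12,
    **kwargs,
) -> synth.ParkProfile:
    defaults = dict(
        peak_month=7,
        image_noise_sd=0.03,
        monthly_counts=(counts,) * 12,
        ad_contamination_rate=0.0,
        duplicate_rate=0.0,
        undersized_rate=0.0,
    )
    defaults.update(kwargs)
    return synth.ParkProfile(name, base, amplitude, **defaults)


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A two-park, one-year corpus with known contamination, built once."""
    out = tmp_path_factory.mktemp("small_corpus")
    profiles = [
        small_profile("Greenwood", 0.33, 0.04, counts=10,
                      duplicate_rate=0.05, undersized_rate=0.03,
                      ad_contamination_rate=0.05),
        small_profile("Flatrock", 0.30, 0.0, counts=8),
    ]
    paths = synth.generate_corpus(
        profiles, out, seed=42, n_months=12, image_size=(24, 24)
    )
    return profiles, paths


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
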