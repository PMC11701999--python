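import numpy as np
import pytest

from bedntcp import DVH, generate_preset


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_bin_dvh():
    """Two point-mass bins: 60 Gy and 80 Gy, half the volume each."""
    return DVH([60.0, 80.0], [30.0, 30.0])


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-patient two-arm synthetic cohort (session-scoped: read-only)."""
    return generate_preset("hypro-like", seed=42, n=200)


@pytest.fixture(scope="session")
def hypro_cohort():
    """Full-size (n=656) two-arm synthetic cohort with default truth."""
    return generate_preset("hypro-like", seed=7)


def random_dvh(rng, n_bins=None, max_dose=80.0):
    """Random valid differential DVH for property tests."""
    n_bins = n_bins or int(rng.integers(1, 60))
    doses = np.sort(rng.uniform(0.5, max_dose, size=n_bins))
    doses += np.arange(n_bins) * 1e-6  # enforce strict increase
    vols = rng.uniform(0.01, 5.0, size=n_bins)
    return DVH(doses, vols)
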