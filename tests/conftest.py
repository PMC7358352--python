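import numpy as np
import pytest

from secmal import (
    DifferentialDVH,
    GeneratorConfig,
    compute_patient,
    generate_cohort,
    load_coefficients,
)


@pytest.fixture(scope="session")
def coeffs():
    return load_coefficients()


@pytest.fixture
def lung_dvh():
    """Three-bin right-lung DVH used by the worked examples."""
    return DifferentialDVH("lung_right", np.array([5.0, 15.0, 30.0]), np.array([0.5, 0.3, 0.2]))


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study cohort: 23 patients, 16 female, seed 42."""
    return generate_cohort(GeneratorConfig())


@pytest.fixture(scope="session")
def default_results(default_cohort, coeffs):
    pairs, _ = default_cohort
    return [compute_patient(pair, coeffs) for pair in pairs]


def random_dvh(rng, organ="lung_right", max_bins=200, max_dose=60.0):
    """Random valid differential DVH for property checks."""
    n = int(rng.integers(1, max_bins + 1))
    doses = np.sort(rng.uniform(0.0, max_dose, size=n))
    doses = np.unique(doses)
    fractions = rng.uniform(0.01, 1.0, size=doses.size)
    return DifferentialDVH(organ, doses, fractions / fractions.sum())


def survival(dvh, thresholds):
    """Volume fraction receiving at least each threshold dose."""
    return np.array([dvh.volume_fractions[dvh.doses >= t].sum() for t in thresholds])
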