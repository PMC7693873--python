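import numpy as np
import pytest

from genosubtype import CohortConfig, fit_variant_logistic, generate_annotation, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The standard synthetic cohort: 200/200, 300 variants, 2 planted subtypes."""
    return generate_cohort(CohortConfig())


@pytest.fixture(scope="session")
def default_annotation():
    return generate_annotation(CohortConfig())


@pytest.fixture(scope="session")
def default_assoc(default_cohort):
    """Per-variant logistic results on the standard cohort (no missing calls)."""
    return fit_variant_logistic(
        default_cohort.genotypes, default_cohort.status.to_numpy(), default_cohort.covariates
    )


@pytest.fixture(scope="session")
def small_cohort_config():
    """A compact cohort for end-to-end pipeline/CLI tests."""
    return CohortConfig(
        n_cases=60, n_controls=60, n_variants=80,
        n_risk_variants=10, n_subtype_variants=15, seed=7,
    )


@pytest.fixture(scope="session")
def block_matrix():
    """6x8 two-block nonnegative matrix: columns 0-3 load rows 0-2, columns 4-7 rows 3-5."""
    A = np.zeros((6, 8))
    rng = np.random.default_rng(42)
    A[:3, :4] = rng.uniform(1.0, 4.0, size=(3, 4))
    A[3:, 4:] = rng.uniform(1.0, 4.0, size=(3, 4))
    return A
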