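import numpy as np
import pytest

from gesdx import GESCohortSpec, GroupedMarkers, generate_cohort


def auc_by_pair_enumeration(diseased, control):
    """Independent O(mn) Mann-Whitney oracle: explicit double loop with the
    half weight on exact ties."""
    total = 0.0
    for w in diseased:
        for v in control:
            if w > v:
                total += 1.0
            elif w == v:
                total += 0.5
    return total / (len(diseased) * len(control))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def normal_two_marker(rng):
    """Well-separated correlated bivariate-normal groups (m=150, n=100)."""
    cov = np.array([[1.0, 0.4], [0.4, 1.5]])
    d = rng.multivariate_normal([1.2, 0.8], cov, 150)
    c = rng.multivariate_normal([0.0, 0.0], cov, 100)
    return GroupedMarkers(d, c, ("h3", "h4"))


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(GESCohortSpec(seed=11))


@pytest.fixture(scope="session")
def rule_cohort():
    return generate_cohort(
        GESCohortSpec(mode="threshold_rule", rule_noise=0.05, seed=23)
    )
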