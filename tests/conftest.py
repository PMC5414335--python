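import numpy as np
import pytest

from regact import compute_iras, median_center, quantile_normalize
from regact.simulate import GeneratorParams, generate_cohort, make_toy_fixtures


@pytest.fixture(scope="session")
def default_cohort():
    """The generator's default study conditions (n=500, 5000 genes, 199 targets)."""
    return generate_cohort(GeneratorParams())


@pytest.fixture(scope="session")
def default_normalized(default_cohort):
    return median_center(quantile_normalize(default_cohort.expression))


@pytest.fixture(scope="session")
def default_iras(default_cohort, default_normalized):
    """Full-signature iRAS on the default cohort (B=1000)."""
    return compute_iras(default_normalized, default_cohort.signature, B=1000, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for unit-level checks."""
    return generate_cohort(GeneratorParams(n_samples=60, n_genes=600, n_targets=40, seed=11))


@pytest.fixture(scope="session")
def small_iras(small_cohort):
    m = median_center(quantile_normalize(small_cohort.expression))
    return compute_iras(m, small_cohort.signature, B=300, seed=5)


@pytest.fixture()
def toy_files(tmp_path):
    return make_toy_fixtures(tmp_path)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; no shared code with the package)
# ---------------------------------------------------------------------------


def brute_force_preliminary(is_target) -> float:
    """Walk every rank position and track the maximal |deviation|, first on ties."""
    is_target = list(is_target)
    n_f = sum(is_target)
    n_b = len(is_target) - n_f
    best = None
    tf = tb = 0
    for flag in is_target:
        if flag:
            tf += 1
        else:
            tb += 1
        d = tf / n_f - tb / n_b
        if best is None or abs(d) > abs(best):
            best = d
    return best


def all_pairs_concordance(scores, labels) -> float:
    """Mann-Whitney concordance probability, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def fisher_two_sided_exhaustive(a, b, c, d) -> float:
    """Two-sided Fisher p by summing hypergeometric point probabilities."""
    from math import comb

    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d

    def pmf(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))
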