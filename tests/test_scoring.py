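import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr
from sklearn.base import clone

from regact import (
    BASEScorer,
    compute_iras,
    normalize_score,
    preliminary_score,
    rank_profile,
    sample_null,
)
from regact.containers import ExpressionMatrix, TargetSignature
from regact.scoring import NullDistribution, _max_deviation

from conftest import brute_force_preliminary


def _matrix(values: dict[str, list[float]], samples=None) -> ExpressionMatrix:
    df = pd.DataFrame(values).T
    df.columns = samples or [f"s{j}" for j in range(df.shape[1])]
    return ExpressionMatrix(df, quantile_normalized=True, median_centered=True)


class TestRankProfile:
    def test_descending_order(self):
        m = _matrix({"A": [2.0], "B": [5.0], "C": [1.0]})
        r = rank_profile(m, "s0")
        assert list(r.genes_in_rank_order) == ["B", "A", "C"]

    def test_all_equal_lexicographic_single_tie_group(self):
        m = _matrix({"B": [1.0], "A": [1.0], "C": [1.0]})
        r = rank_profile(m, "s0")
        assert list(r.genes_in_rank_order) == ["A", "B", "C"]
        assert len(set(r.tie_group_ids)) == 1

    def test_row_order_invariance(self):
        m1 = _matrix({"A": [3.0], "B": [1.0], "C": [2.0]})
        m2 = _matrix({"C": [2.0], "B": [1.0], "A": [3.0]})
        assert list(rank_profile(m1, "s0").genes_in_rank_order) == list(
            rank_profile(m2, "s0").genes_in_rank_order
        )

    def test_unknown_sample(self):
        with pytest.raises(KeyError):
            rank_profile(_matrix({"A": [1.0]}), "nope")


class TestPreliminaryScore:
    def _profile_with_targets_at(self, ranks, n=10):
        values = {f"g{i:02d}": [float(n - i)] for i in range(n)}
        m = _matrix(values)
        r = rank_profile(m, "s0")
        sig = TargetSignature("t", [r.genes_in_rank_order[k - 1] for k in ranks])
        return r, sig

    def test_perfect_enrichment_is_one(self):
        r, sig = self._profile_with_targets_at([1, 2, 3])
        assert preliminary_score(r, sig) == 1.0

    def test_perfect_depletion_is_minus_one(self):
        r, sig = self._profile_with_targets_at([8, 9, 10])
        assert preliminary_score(r, sig) == -1.0

    def test_mixed_ranks_match_brute_force(self):
        r, sig = self._profile_with_targets_at([1, 4, 9])
        is_target = [g in set(sig.genes) for g in r.genes_in_rank_order]
        assert preliminary_score(r, sig) == brute_force_preliminary(is_target)

    def test_zero_overlap_is_error(self):
        r, _ = self._profile_with_targets_at([1])
        with pytest.raises(ValueError, match="no genes"):
            preliminary_score(r, TargetSignature("x", ["absent"]))

    @settings(deadline=None, max_examples=250, derandomize=True)
    @given(st.integers(3, 50), st.integers(1, 10), st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_random_profiles(self, n, n_targets, seed):
        """The production statistic equals the exhaustive walk, exactly."""
        n_targets = min(n_targets, n - 1)
        rng = np.random.default_rng(seed)
        is_target = np.zeros(n, dtype=bool)
        is_target[rng.choice(n, n_targets, replace=False)] = True
        assert _max_deviation(is_target) == brute_force_preliminary(is_target)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(3, 40), st.integers(1, 8), st.integers(0, 2**31 - 1))
    def test_bounds_and_extremes(self, n, n_targets, seed):
        n_targets = min(n_targets, n - 1)
        rng = np.random.default_rng(seed)
        is_target = np.zeros(n, dtype=bool)
        is_target[rng.choice(n, n_targets, replace=False)] = True
        d = _max_deviation(is_target)
        assert -1.0 <= d <= 1.0
        if is_target[:n_targets].all():
            assert d == 1.0
        if is_target[n - n_targets:].all():
            assert d == -1.0

    def test_monotonicity_under_target_upshift(self):
        rng = np.random.default_rng(42)
        genes = [f"g{i:02d}" for i in range(30)]
        targets = genes[::5]
        vals = rng.normal(size=30)
        for delta in (0.1, 0.5, 2.0, 10.0):
            shifted = vals + delta * np.isin(genes, targets)
            before = _score_of(genes, vals, targets)
            after = _score_of(genes, shifted, targets)
            assert after >= before


def _score_of(genes, vals, targets):
    m = ExpressionMatrix(
        pd.DataFrame({"s0": vals}, index=genes),
        quantile_normalized=True,
        median_centered=True,
    )
    return preliminary_score(rank_profile(m, "s0"), TargetSignature("t", targets))


class TestSampleNull:
    def test_default_size_and_determinism(self):
        a = sample_null(100, set_size=10, B=50, seed=3)
        b = sample_null(100, set_size=10, B=50, seed=3)
        assert a.B == 50
        assert np.array_equal(a.scores, b.scores)

    def test_near_degenerate_set_size(self):
        null = sample_null(20, set_size=19, B=25, seed=0)
        assert np.isfinite(null.scores).all()

    def test_out_of_range_set_size(self):
        with pytest.raises(ValueError):
            sample_null(10, set_size=10, B=5, seed=0)

    def test_null_symmetric_about_zero(self):
        null = sample_null(2000, set_size=20, B=1000, seed=1)
        se = null.scores.std(ddof=1) / np.sqrt(null.B)
        assert abs(null.scores.mean()) < 3 * se


class TestNormalizeScore:
    def _null(self, scores):
        return NullDistribution(np.asarray(scores, dtype=float), set_size=3)

    def test_zero_prelim_gives_zero(self):
        assert normalize_score(0.0, self._null([0.2, -0.2])) == 0.0

    def test_positive_stratum_arithmetic(self):
        assert normalize_score(0.6, self._null([0.2, 0.2, -0.5])) == pytest.approx(3.0)

    def test_negative_stratum_preserves_sign(self):
        assert normalize_score(-0.4, self._null([0.3, -0.2, -0.2])) == pytest.approx(-2.0)

    def test_empty_stratum_is_error(self):
        with pytest.raises(ValueError, match="increase B"):
            normalize_score(0.5, self._null([-0.1, -0.2]))

    def test_literal_mode_divides_by_overall_mean(self):
        null = self._null([0.4, 0.2])
        assert normalize_score(0.6, null, sign_stratified=False) == pytest.approx(2.0)


class TestComputeIras:
    def test_sample_with_targets_on_top_has_largest_iras(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i:02d}" for i in range(30)]
        targets = genes[:6]
        vals = rng.normal(size=(30, 5))
        vals[:6, 0] = vals.max() + 1 + rng.random(6)  # sample s0: all targets on top
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=genes, columns=[f"s{j}" for j in range(5)]),
            quantile_normalized=True,
            median_centered=True,
        )
        vec = compute_iras(m, TargetSignature("t", targets), B=200, seed=1)
        assert int(np.argmax(vec.iras)) == 0

    def test_sign_consistency_and_finiteness(self, small_iras):
        assert np.isfinite(small_iras.iras).all()
        assert np.array_equal(np.sign(small_iras.iras), np.sign(small_iras.preliminary))

    def test_seed_determinism_bitwise(self, small_cohort):
        from regact import median_center, quantile_normalize

        m = median_center(quantile_normalize(small_cohort.expression))
        a = compute_iras(m, small_cohort.signature, B=100, seed=9)
        b = compute_iras(m, small_cohort.signature, B=100, seed=9)
        assert np.array_equal(a.iras, b.iras)
        assert np.array_equal(a.preliminary, b.preliminary)

    def test_recovers_planted_activity(self, small_cohort, small_iras):
        rho = spearmanr(small_iras.iras, small_cohort.truth["activity"]).statistic
        assert rho >= 0.9


class TestBASEScorer:
    def test_sklearn_api_round_trip(self, small_cohort, small_iras):
        from regact import median_center, quantile_normalize

        X = median_center(quantile_normalize(small_cohort.expression)).to_samples_by_genes()
        scorer = BASEScorer(
            target_genes=list(small_cohort.signature.genes), n_permutations=300, random_state=5
        )
        out = clone(scorer).fit(X).transform(X)
        assert out.shape == (len(X), 1)
        assert np.array_equal(out[:, 0], small_iras.iras)

    def test_requires_dataframe_and_overlap(self):
        with pytest.raises(TypeError):
            BASEScorer(target_genes=["A"]).fit(np.zeros((3, 4)))
        X = pd.DataFrame(np.zeros((3, 2)), columns=["G1", "G2"])
        with pytest.raises(ValueError, match="no genes"):
            BASEScorer(target_genes=["absent"]).fit(X)
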