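import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gwasint.exceptions import ValidationError
from gwasint.integrate import (
    apply_weights,
    estimate_pi0,
    fisher_combine,
    make_weights,
    meta_combine,
    qvalues,
    sfdr_adjust,
    sfdr_weights,
    stratify_by_score,
)


class TestMetaCombine:
    def test_equal_unit_variances(self):
        z_meta, _ = meta_combine([1.0], [1.0])
        assert z_meta == pytest.approx([np.sqrt(2)])
        z_meta, _ = meta_combine([1.5], [0.0])
        assert z_meta == pytest.approx([1.5 / np.sqrt(2)])

    def test_inverse_variance_weighting(self):
        z_meta, p = meta_combine([2.0], [1.0], v=[1.0], v_add=[4.0])
        assert z_meta == pytest.approx([2.23606798])
        assert p == pytest.approx([2 * 0.0126736], rel=1e-3)

    def test_zero_annotation_preserves_ranking(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(200)
        _, p = meta_combine(z, np.zeros(200))
        assert np.array_equal(np.argsort(p), np.argsort(-np.abs(z)))

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValidationError):
            meta_combine([1.0], [1.0], v=[0.0])


class TestFisherCombine:
    def test_boundary_and_hand_values(self):
        stat, p = fisher_combine([1.0, 0.05], [1.0, 0.05])
        assert stat[0] == pytest.approx(0.0) and p[0] == pytest.approx(1.0)
        assert stat[1] == pytest.approx(11.98293, abs=1e-4)
        assert p[1] == pytest.approx(0.0174787, abs=1e-6)

    def test_combined_p_decreasing_in_stat(self):
        stat, p = fisher_combine(
            np.linspace(0.01, 0.99, 25), np.full(25, 0.5)
        )
        order = np.argsort(stat)
        assert np.all(np.diff(p[order]) < 0)

    def test_unit_p_add_preserves_ranking(self):
        rng = np.random.default_rng(1)
        p = rng.random(300)
        _, comb = fisher_combine(p, np.ones(300))
        assert np.array_equal(np.argsort(comb), np.argsort(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fisher_combine([0.0], [0.5])


class TestMakeWeights:
    def test_equal_scores_give_unit_weights(self):
        assert make_weights(np.full(7, 3.3)).w == pytest.approx(np.ones(7))

    def test_cumulative_hand_values(self):
        w = make_weights(np.array([0.0, 2.0, 4.0]), beta=2.0, scheme="cumulative").w
        assert w == pytest.approx([0.04550026, 1.0, 1.95449974], abs=1e-6)

    def test_exponential_overflow_safe(self):
        w = make_weights(np.array([0.0, 40.0, 80.0]), beta=2.0, scheme="exponential").w
        assert np.all(np.isfinite(w)) and w.mean() == pytest.approx(1.0)
        assert w[2] == pytest.approx(3.0)  # winner takes all

    @given(st.lists(st.floats(-10, 80), min_size=1, max_size=60))
    @settings(max_examples=80, deadline=None)
    def test_mean_one_invariant(self, scores):
        for scheme in ("cumulative", "exponential"):
            w = make_weights(np.asarray(scores), beta=2.0, scheme=scheme).w
            assert np.all(w >= 0)
            assert w.mean() == pytest.approx(1.0, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            make_weights([np.nan, 1.0])


class TestApplyWeights:
    def test_unit_cap_and_zero_weight(self):
        out = apply_weights(np.array([0.01, 0.8, 0.3]), np.array([1.0, 0.5, 0.0]))
        assert out == pytest.approx([0.01, 1.0, 1.0])

    def test_elementwise_division(self):
        w = make_weights(np.array([0.0, 2.0, 4.0]), beta=2.0)
        out = apply_weights(np.full(3, 1e-4), w)
        assert out == pytest.approx([2.1978e-3, 1e-4, 5.1164e-5], rel=1e-3)

    def test_weighted_bonferroni_controls_fwer(self):
        # for ANY fixed mean-one weights and iid uniform p, rejecting
        # p/w < alpha/m keeps the family-wise error near/below alpha
        rng = np.random.default_rng(42)
        m, reps, alpha = 40, 20_000, 0.05
        w = make_weights(rng.standard_normal(m) * 3, beta=2.0).w
        p = rng.random((reps, m))
        fwer = np.mean((p / np.maximum(w, 1e-12) < alpha / m).any(axis=1))
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert fwer <= alpha + 3 * se


class TestEstimatePi0:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.1, 0.2, 0.6, 0.8], 1.0),
            ([0.01, 0.2, 0.3, 0.7], 0.5),
            ([0.01, 0.02, 0.03, 0.04], 1 / 2),  # clamp floor 1/(0.5*4)
        ],
    )
    def test_values(self, p, expected):
        assert estimate_pi0(p) == pytest.approx(expected)


class TestQvalues:
    def test_single_p(self):
        assert qvalues([0.2], 0.7) == pytest.approx([0.14])

    def test_hand_unrolled_recursion(self):
        q = qvalues([0.01, 0.04, 0.5, 0.9], pi0=0.5)
        assert q == pytest.approx([0.02, 0.04, 1 / 3, 0.45])

    def test_matches_bruteforce_minimum(self):
        # oracle: q_(i) = min over j >= i of pi0*m*p_(j)/j, undone to input order
        rng = np.random.default_rng(5)
        for _ in range(200):
            m = int(rng.integers(1, 50))
            p = rng.random(m)
            pi0 = float(rng.uniform(0.1, 1.0))
            order = np.argsort(p, kind="stable")
            ps = p[order]
            brute_sorted = [
                min(pi0 * m * ps[j] / (j + 1) for j in range(i, m)) for i in range(m)
            ]
            brute = np.empty(m)
            brute[order] = brute_sorted
            assert np.allclose(qvalues(p, pi0), brute)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(6)
        p = rng.random(500)
        q = qvalues(p, 0.8)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= 0)


class TestStratify:
    def test_two_group_sizes(self):
        rng = np.random.default_rng(0)
        groups = stratify_by_score(rng.random(100), k=2, top_fraction=0.05)
        assert (groups == 1).sum() == 5 and (groups == 2).sum() == 95

    def test_top_group_has_highest_scores(self):
        scores = np.arange(40.0)
        groups = stratify_by_score(scores, k=2, top_fraction=0.1)
        assert set(np.flatnonzero(groups == 1)) == {36, 37, 38, 39}

    def test_ties_stable_at_cutoff(self):
        scores = np.array([5.0] * 10)
        groups = stratify_by_score(scores, k=2, top_fraction=0.05)
        assert groups[0] == 1 and (groups == 1).sum() == 1

    def test_multigroup_quantile_split(self):
        groups = stratify_by_score(np.arange(100.0), k=4, top_fraction=0.05)
        sizes = [(groups == g).sum() for g in (1, 2, 3, 4)]
        assert sizes[0] == 5 and sorted(sizes[1:]) == [31, 32, 32]
        # groups ordered by decreasing score
        assert groups[99] == 1 and groups[0] == 4

    def test_k_exceeding_m_rejected(self):
        with pytest.raises(ValidationError):
            stratify_by_score([1.0, 2.0], k=3)


class TestSfdrWeights:
    def test_no_rejections_reduces_to_unweighted(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.2, 1.0, size=60)
        groups = np.r_[np.ones(10, int), np.full(50, 2)]
        fit = sfdr_weights(p, groups, gamma=0.05)
        assert fit.w_k == pytest.approx([1.0, 1.0])

    def test_single_rejecting_group_takes_all_weight(self):
        p = np.r_[[1e-9], np.random.default_rng(3).uniform(0.3, 1.0, 39)]
        groups = np.r_[np.ones(4, int), np.full(36, 2)]
        fit = sfdr_weights(p, groups, gamma=0.05)
        assert fit.w_k[0] == pytest.approx(40 / 4)
        assert fit.w_k[1] == 0.0

    def test_both_groups_reject_hand_values(self):
        # alpha = (0.01, 0.001), sizes (2, 8): w = (3.5714, 0.35714)
        p = np.array([1e-6, 0.01, 1e-7, 0.001, 0.9, 0.8, 0.7, 0.95, 0.85, 0.75])
        groups = np.array([1, 1, 2, 2, 2, 2, 2, 2, 2, 2])
        fit = sfdr_weights(p, groups, gamma=0.5)
        assert fit.alpha_k == pytest.approx([0.01, 0.001])
        assert fit.w_k == pytest.approx([3.571429, 0.357143], rel=1e-5)
        m = len(p)
        assert np.sum(fit.w_k * fit.m_k) / m == pytest.approx(1.0)


class TestSfdrAdjust:
    def test_uninformative_case_is_identity(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.2, 1.0, size=200)
        scores = rng.random(200)
        p_sfdr, fit = sfdr_adjust(p, scores)
        assert np.allclose(p_sfdr, p)

    def test_weighted_division_and_cap(self):
        # same configuration as the hand-computed sfdr_weights example
        p = np.array([1e-6, 0.01, 1e-7, 0.001, 0.9, 0.8, 0.7, 0.95, 0.85, 0.75])
        scores = np.array([9.0, 8.0, 5.0, 4.5, 4.0, 3.5, 3.0, 2.5, 2.0, 1.5])
        p_sfdr, fit = sfdr_adjust(p, scores, top_fraction=0.2, gamma=0.5)
        assert fit.w_k == pytest.approx([3.571429, 0.357143], rel=1e-5)
        assert p_sfdr[0] == pytest.approx(1e-6 / 3.571429, rel=1e-5)
        assert p_sfdr[4] == 1.0  # 0.9 / 0.357 caps at one
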