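import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2, kstest

from gwasint.annotation import (
    PHRED_CHI2_SCALE,
    inverse_normal_rescale,
    permute_scores,
    phred_scale,
    rank_uniform_p,
    similarity,
)
from gwasint.exceptions import ValidationError


class TestPhredScale:
    def test_quantile_interpretation(self):
        # top 10% boundary -> 10, top 1% -> 20, least deleterious -> 0
        raw = np.arange(100, dtype=float)
        phred = phred_scale(raw)
        assert phred[raw == 90] == pytest.approx(10.0)  # rank 10 of 100
        assert phred[raw == 99] == pytest.approx(20.0)  # rank 1 of 100
        assert phred[raw == 0] == pytest.approx(0.0)  # lowest score
        assert np.all(phred >= 0)

    def test_rank_direction(self):
        phred = phred_scale([5.0, 1.0, 3.0])
        assert np.argmax(phred) == 0 and np.argmin(phred) == 1

    @given(
        st.lists(st.integers(-1000, 1000), min_size=2, max_size=40, unique=True),
        st.sampled_from([np.exp, np.arctan, lambda x: 3 * x + 1]),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_increasing_transform(self, raw, f):
        raw = np.asarray(raw, dtype=float) / 100.0  # distinct within [-10, 10]
        assert np.allclose(phred_scale(raw), phred_scale(f(raw)))

    def test_matches_scaled_chi2_distribution(self):
        # phred / ((10/ln10)/2) should look chi-square with 2 df
        rng = np.random.default_rng(0)
        phred = phred_scale(rng.standard_normal(100_000))
        stat = kstest(phred / PHRED_CHI2_SCALE, chi2(df=2).cdf)
        assert stat.pvalue > 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            phred_scale([])


class TestRankUniformP:
    def test_grid_and_direction(self):
        p = rank_uniform_p([10.0, 40.0, 20.0, 30.0])
        assert p.tolist() == [1.0, 0.25, 0.75, 0.5]

    def test_ties_stable_by_input_order(self):
        p = rank_uniform_p([5.0, 5.0, 1.0])
        assert p == pytest.approx([1 / 3, 2 / 3, 1.0])


class TestInverseNormalRescale:
    def test_single_score_maps_to_zero(self):
        assert inverse_normal_rescale([3.0], [5.0]) == pytest.approx([0.0])

    def test_two_scores_signed_quantiles(self):
        # ascending quantiles (-0.6745, +0.6745); direction follows z
        z_add = inverse_normal_rescale([1.0, 9.0], [-1.0, 3.0])
        assert z_add == pytest.approx([0.6744898, 0.6744898], abs=1e-6)
        z_add = inverse_normal_rescale([1.0, 9.0], [1.0, 3.0])
        assert z_add == pytest.approx([-0.6744898, 0.6744898], abs=1e-6)

    def test_magnitude_multiset_is_the_quantile_grid(self):
        rng = np.random.default_rng(1)
        raw = rng.random(101)
        z = rng.standard_normal(101)
        from scipy.special import ndtri

        grid = np.abs(ndtri((np.arange(1, 102) - 0.5) / 101))
        out = inverse_normal_rescale(raw, z)
        assert np.allclose(np.sort(np.abs(out)), np.sort(grid))

    def test_sign_of_zero_is_positive(self):
        out = inverse_normal_rescale([1.0, 2.0], [0.0, 0.0])
        assert out[1] > 0  # top score, z = 0 -> positive direction

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            inverse_normal_rescale([1.0, 2.0], [1.0])


class TestSimilarity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(7.0, 7.0, 1.0), (10.0, 30.0, 0.5), (1e-9, 5.0, pytest.approx(0.0, abs=1e-9))],
    )
    def test_values(self, a, b, expected):
        assert similarity(a, b) == pytest.approx(expected)

    @given(st.floats(0.01, 100), st.floats(0.01, 100), st.floats(0.01, 50))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_scale_invariant(self, a, b, lam):
        assert similarity(a, b) == pytest.approx(similarity(b, a))
        assert similarity(lam * a, lam * b) == pytest.approx(similarity(a, b))
        assert 0.0 <= similarity(a, b) <= 1.0

    def test_both_zero_undefined(self):
        with pytest.raises(ValidationError):
            similarity(0.0, 0.0)


class TestPermuteScores:
    def _track(self, m=50, seed=0):
        rng = np.random.default_rng(seed)
        raw = rng.random(m)
        return pd.DataFrame(
            {"snp_id": [f"s{i}" for i in range(m)], "raw": raw, "phred": phred_scale(raw)}
        )

    def test_deterministic_and_conserving(self):
        track = self._track()
        a = permute_scores(track, seed=7)
        b = permute_scores(track, seed=7)
        pd.testing.assert_frame_equal(a, b)
        assert sorted(a["phred"]) == sorted(track["phred"])
        assert list(a["snp_id"]) == list(track["snp_id"])
        # raw and phred move together: phred still the phred of raw
        assert np.allclose(a["phred"], phred_scale(a["raw"].to_numpy()))

    def test_length_one_is_identity(self):
        track = self._track(m=1)
        pd.testing.assert_frame_equal(permute_scores(track, 3), track)

    def test_breaks_association_with_z(self):
        # after permutation, scores are independent of any per-SNP signal
        rng = np.random.default_rng(3)
        m = 100_000
        raw = rng.random(m)
        track = pd.DataFrame(
            {"snp_id": [f"s{i}" for i in range(m)], "raw": raw, "phred": phred_scale(raw)}
        )
        absz = np.abs(np.sort(rng.standard_normal(m)))  # strongly ordered
        permuted = permute_scores(track, seed=9)
        corr = np.corrcoef(permuted["phred"], absz)[0, 1]
        assert abs(corr) < 0.01
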