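import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from mockdebias import (
    aitchison,
    bias_reduction_report,
    bray_curtis,
    spearman,
    wilcoxon_signed_rank,
)
from mockdebias.bias import close


def _s(values, taxa=None):
    taxa = taxa or [f"t{i}" for i in range(len(values))]
    return pd.Series(values, index=taxa, dtype=float)


def enumerate_signed_rank_p(d, alternative):
    """Full 2^n enumeration of the signed-rank null (test oracle)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ge = le = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        ge += w >= w_obs - 1e-9
        le += w <= w_obs + 1e-9
    p_ge, p_le = ge / 2**n, le / 2**n
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


class TestBrayCurtis:
    def test_examples(self):
        assert bray_curtis(_s([0.5, 0.5]), _s([0.5, 0.5])) == 0.0
        assert bray_curtis(_s([1, 0]), _s([0, 1])) == 1.0
        assert bray_curtis(_s([0.5, 0.5]), _s([1.0, 0.0])) == pytest.approx(0.5)

    def test_equals_half_l1_on_closed_vectors_and_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            k = rng.integers(2, 10)
            x = close(_s(rng.dirichlet(np.ones(k))))
            y = close(_s(rng.dirichlet(np.ones(k)), taxa=list(x.index)))
            d = bray_curtis(x, y)
            assert d == pytest.approx(0.5 * np.abs(x - y).sum(), abs=1e-12)
            assert d == pytest.approx(scipy_braycurtis(x, y), abs=1e-12)
            assert d == pytest.approx(bray_curtis(y, x), abs=1e-12)
            assert 0 <= d <= 1

    def test_mismatched_taxa_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(_s([1, 0], taxa=["a", "b"]), _s([1, 0], taxa=["a", "c"]))


class TestAitchison:
    def test_identity_and_scale_invariance(self):
        x = _s([0.2, 0.3, 0.5])
        assert aitchison(x, x) == pytest.approx(0.0, abs=1e-12)
        assert aitchison(x, 7.0 * x) == pytest.approx(0.0, abs=1e-12)

    def test_direct_clr_oracle(self):
        x = close(_s([1, 1, 2]))
        y = close(_s([2, 1, 1]))
        # independent clr computation
        lx = np.log(x.to_numpy())
        ly = np.log(y.to_numpy())
        expected = np.linalg.norm((lx - lx.mean()) - (ly - ly.mean()))
        assert aitchison(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zeros_replaced_before_transform(self):
        x = _s([0.5, 0.5, 0.0])
        y = _s([0.4, 0.6, 0.0])
        assert math.isfinite(aitchison(x, y))

    def test_symmetry_property(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = close(_s(rng.dirichlet(np.ones(5))))
            y = close(_s(rng.dirichlet(np.ones(5)), taxa=list(x.index)))
            assert aitchison(x, y) == pytest.approx(aitchison(y, x), abs=1e-12)


class TestWilcoxon:
    def test_all_reduced_n5_exact(self):
        before = [5.0, 4.0, 3.0, 2.0, 1.0]
        after = [4.0, 3.0, 2.0, 1.0, 0.5]
        _, p = wilcoxon_signed_rank(before, after, alternative="greater")
        assert p == pytest.approx(1 / 32)

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError, match="all differences zero"):
            wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])

    @pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
    def test_mixed_signs_n6_matches_enumeration(self, alternative):
        before = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        after = np.array([2.0, 1.4, 1.0, 5.0, 3.0, 2.7])
        _, p = wilcoxon_signed_rank(before, after, alternative=alternative)
        assert p == pytest.approx(enumerate_signed_rank_p(before - after, alternative), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            d = rng.normal(0.3, 1.0, 12)
            d = d[d != 0]
            _, p = wilcoxon_signed_rank(d, np.zeros_like(d), alternative="two-sided")
            ref = sps.wilcoxon(d, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_ties_midranked_and_exact(self):
        before = np.array([2.0, 2.0, 3.0, 3.0, 5.0])
        after = np.array([1.0, 1.0, 2.0, 4.0, 4.0])
        _, p = wilcoxon_signed_rank(before, after, alternative="greater")
        assert p == pytest.approx(enumerate_signed_rank_p(before - after, "greater"), abs=1e-12)


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        rho, p = spearman([0.1, 0.2, 0.3, 0.4, 0.5], x)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)  # 2 of 5! permutations reach |rho| = 1
        rho, _ = spearman([0.5, 0.4, 0.3, 0.2, 0.1], x)
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_exact_p_matches_scipy_permutation_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=6)
        y = 0.5 * x + rng.normal(size=6)
        rho, p = spearman(x, y)

        def statistic(perm_y):
            return sps.spearmanr(x, perm_y).statistic

        ref = sps.permutation_test(
            (y,),
            statistic,
            permutation_type="pairings",
            alternative="two-sided",
            n_resamples=math.factorial(6),
        )
        assert rho == pytest.approx(sps.spearmanr(x, y).statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)


class TestBiasReductionReport:
    def _distances(self, before, after):
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(len(before))],
            "protocol": ["P"] * len(before),
            "distance_before": before,
            "distance_after": after,
        })

    def test_identity_correction_zero_reduction(self):
        d = self._distances([0.3, 0.2, 0.4, 0.25], [0.3, 0.2, 0.4, 0.25])
        rep = bias_reduction_report(d, strata=["protocol"])
        row = rep.summary.iloc[0]
        assert row["pct_reduction_of_medians"] == pytest.approx(0.0)
        assert math.isnan(row["p_wilcoxon"])  # no nonzero differences

    def test_exact_cancellation_full_reduction(self):
        d = self._distances([0.3, 0.2, 0.4, 0.25, 0.5], [0.0, 0.0, 0.0, 0.0, 0.0])
        rep = bias_reduction_report(d, strata=["protocol"])
        row = rep.summary.iloc[0]
        assert row["pct_reduction_of_medians"] == pytest.approx(100.0)
        assert row["median_pct_reduction"] == pytest.approx(100.0)
        assert row["p_wilcoxon"] == pytest.approx(1 / 32)

    def test_small_stratum_omits_p_keeps_medians(self):
        d = self._distances([0.3, 0.2, 0.4], [0.1, 0.1, 0.1])
        rep = bias_reduction_report(d, strata=["protocol"])
        row = rep.summary.iloc[0]
        assert math.isnan(row["p_wilcoxon"])
        assert row["median_before"] == pytest.approx(0.3)
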