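import numpy as np
import pandas as pd
import pytest

from mockdebias import (
    PipelineConfig,
    build_reference_composition,
    estimate_sample_bias,
    pool_protocol_bias,
    select_evaluable_taxa,
)
from mockdebias.bias import ReferenceComposition, center_to_gm1, close, geometric_mean


def _comp(values, taxa=None):
    taxa = taxa or [f"t{i}" for i in range(len(values))]
    return close(pd.Series(values, index=taxa, dtype=float))


class TestReferenceComposition:
    def test_single_replicate_is_reclosed(self):
        ref = build_reference_composition([pd.Series({"a": 0.2, "b": 0.6})])
        assert ref.composition.sum() == pytest.approx(1.0)
        assert ref.composition["b"] / ref.composition["a"] == pytest.approx(3.0)

    def test_identical_replicates_unchanged(self):
        r = _comp([0.5, 0.5])
        ref = build_reference_composition([r, r])
        assert ref.composition.tolist() == pytest.approx([0.5, 0.5])

    def test_geometric_mean_symmetry(self):
        # gm of (0.8, 0.2) and (0.2, 0.8) is equal per taxon -> (0.5, 0.5)
        ref = build_reference_composition([_comp([0.8, 0.2]), _comp([0.2, 0.8])])
        assert ref.composition.tolist() == pytest.approx([0.5, 0.5])

    def test_zero_taxon_excluded_with_warning(self, caplog):
        ref = build_reference_composition([_comp([0.5, 0.5, 0.0])])
        assert list(ref.composition.index) == ["t0", "t1"]


class TestSelectEvaluableTaxa:
    def test_even_mock_keeps_all(self, config):
        ref = ReferenceComposition("dna_mock", _comp([1] * 8))
        assert len(select_evaluable_taxa(ref, "even_mock", config)) == 8

    def test_staggered_threshold(self, config):
        expected = _comp([0.9, 0.09, 0.009, 0.0009, 0.0005], taxa=list("abcde"))
        ref = ReferenceComposition("dna_mock", expected)
        kept = select_evaluable_taxa(ref, "staggered_mock", config, expected=expected)
        assert kept == ["a", "b", "c", "d"]


class TestEstimateSampleBias:
    def test_no_bias_gives_ones(self):
        ref = ReferenceComposition("dna_mock", _comp([1, 1, 1, 1]))
        b = estimate_sample_bias(ref.composition, ref, list(ref.composition.index))
        assert np.allclose(b, 1.0)

    def test_hand_computed_centered_ratio(self):
        ref = ReferenceComposition("dna_mock", _comp([0.25] * 4))
        observed = close(ref.composition * [2, 1, 1, 0.5])
        b = estimate_sample_bias(observed, ref, list(ref.composition.index))
        # gm(2,1,1,0.5) = 1, so the centered bias is the ratio itself
        assert b.tolist() == pytest.approx([2, 1, 1, 0.5])

    def test_scale_invariance(self):
        ref = ReferenceComposition("dna_mock", _comp([0.4, 0.3, 0.3]))
        observed = ref.composition * [3.0, 1.0, 0.2]
        b1 = estimate_sample_bias(observed, ref, list(ref.composition.index))
        b2 = estimate_sample_bias(observed * 17.3, ref, list(ref.composition.index))
        assert np.allclose(b1, b2)

    def test_zero_taxa_dropped_and_sparse_sample_excluded(self):
        ref = ReferenceComposition("dna_mock", _comp([1, 1, 1]))
        obs = pd.Series({"t0": 0.7, "t1": 0.3, "t2": 0.0})
        b = estimate_sample_bias(obs, ref, list(ref.composition.index))
        assert list(b.index) == ["t0", "t1"]
        assert estimate_sample_bias(pd.Series({"t0": 1.0, "t1": 0.0, "t2": 0.0}), ref, list(ref.composition.index)) is None

    def test_exact_recovery_of_planted_bias(self):
        """Noiseless observed ∝ reference ⊙ B returns B to machine precision."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = rng.integers(3, 10)
            ref = ReferenceComposition("dna_mock", _comp(rng.dirichlet(np.ones(k))))
            bias = center_to_gm1(pd.Series(np.exp(rng.normal(0, 1, k)), index=ref.composition.index))
            observed = close(ref.composition * bias)
            est = estimate_sample_bias(observed, ref, list(ref.composition.index))
            assert np.allclose(np.log(est), np.log(bias), atol=1e-12)

    def test_subcompositional_coherence(self):
        rng = np.random.default_rng(1)
        ref = ReferenceComposition("dna_mock", _comp(rng.dirichlet(np.ones(6))))
        bias = center_to_gm1(pd.Series(np.exp(rng.normal(0, 0.5, 6)), index=ref.composition.index))
        observed = close(ref.composition * bias)
        taxa = list(ref.composition.index)
        sub = taxa[:4]
        direct = estimate_sample_bias(observed, ref, sub)
        full = estimate_sample_bias(observed, ref, taxa)
        restricted = center_to_gm1(full[sub])
        assert np.allclose(np.log(direct), np.log(restricted), atol=1e-12)


class TestPooling:
    def test_single_sample_passthrough(self):
        v = center_to_gm1(pd.Series({"a": 2.0, "b": 0.5}))
        assert pool_protocol_bias([v]).tolist() == pytest.approx(v.tolist())

    def test_opposite_biases_cancel(self):
        a = pd.Series({"a": 2.0, "b": 0.5})
        b = pd.Series({"a": 0.5, "b": 2.0})
        assert pool_protocol_bias([a, b]).tolist() == pytest.approx([1.0, 1.0])

    def test_centering_invariant(self):
        rng = np.random.default_rng(2)
        vecs = [
            center_to_gm1(pd.Series(np.exp(rng.normal(0, 1, 5)), index=list("abcde")))
            for _ in range(6)
        ]
        pooled = pool_protocol_bias(vecs)
        assert np.prod(pooled.to_numpy()) == pytest.approx(1.0, abs=1e-9)

    def test_noisy_pooling_recovers_truth_within_5pct(self):
        """Multinomial replicates around a known bias pool to the truth."""
        rng = np.random.default_rng(3)
        taxa = ["a", "b", "c"]
        truth = center_to_gm1(pd.Series([2.0, 1.0, 0.5], index=taxa))
        ref = ReferenceComposition("dna_mock", _comp([1, 1, 1], taxa=taxa))
        depth = 100_000
        samples = []
        for _ in range(4):
            p = close(ref.composition * truth)
            counts = rng.multinomial(depth, p.to_numpy())
            obs = pd.Series(counts, index=taxa, dtype=float)
            samples.append(estimate_sample_bias(close(obs), ref, taxa))
        pooled = pool_protocol_bias(samples)
        assert np.allclose(pooled, truth, rtol=0.05)

    def test_pooled_error_shrinks_with_replicates(self):
        """Log-scale RMSE of the pooled estimate decreases from 1 to 8 replicates."""
        rng = np.random.default_rng(4)
        taxa = list("abcd")
        truth = center_to_gm1(pd.Series(np.exp(rng.normal(0, 0.8, 4)), index=taxa))
        ref = ReferenceComposition("dna_mock", _comp([1, 1, 1, 1], taxa=taxa))
        p = close(ref.composition * truth).to_numpy()

        def rmse(n_reps, trial_rng):
            samples = []
            for _ in range(n_reps):
                counts = trial_rng.multinomial(2000, p)
                obs = pd.Series(counts, index=taxa, dtype=float)
                est = estimate_sample_bias(close(obs), ref, taxa)
                if est is not None and len(est) == 4:
                    samples.append(est)
            pooled = pool_protocol_bias(samples)
            return np.sqrt(np.mean((np.log(pooled) - np.log(truth)) ** 2))

        err1 = np.mean([rmse(1, np.random.default_rng(100 + i)) for i in range(30)])
        err8 = np.mean([rmse(8, np.random.default_rng(200 + i)) for i in range(30)])
        assert err8 < err1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool_protocol_bias([])
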