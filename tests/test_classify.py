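import math

import numpy as np
import pytest

from mockdebias import (
    PipelineConfig,
    ReferenceSet,
    classify_asv,
    classify_table,
    collapse_to_species,
    detect_chimera,
    levenshtein,
    min_lv_to_references,
    resolve_ambiguous,
)
from mockdebias.classify import AMBIGUOUS, LcsIndex, jukes_cantor_distance

from conftest import recursive_levenshtein


def _substitute(seq, positions, rng=None):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestLevenshtein:
    def test_identity_and_empty(self):
        assert levenshtein("ACGT", "ACGT") == 0
        assert levenshtein("", "ACG") == 3
        assert levenshtein("ACG", "") == 3
        assert levenshtein("", "") == 0

    def test_matches_recursive_oracle_on_random_acgt_pairs(self):
        rng = np.random.default_rng(2024)
        bases = np.array(list("ACGT"))
        for _ in range(200):
            a = "".join(rng.choice(bases, size=rng.integers(0, 11)))
            b = "".join(rng.choice(bases, size=rng.integers(0, 11)))
            assert levenshtein(a, b) == recursive_levenshtein(a, b)

    def test_symmetry_and_triangle(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        seqs = ["".join(rng.choice(bases, size=8)) for _ in range(10)]
        for a in seqs:
            for b in seqs:
                assert levenshtein(a, b) == levenshtein(b, a)
                for c in seqs:
                    assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


class TestMinLv:
    REFS = ReferenceSet(
        variants={
            "Alpha": ["ACGTACGTACGT", "ACGTACGTACGA"],
            "Beta": ["TTTTGGGGCCCC"],
        },
        trim_len=12,
    )

    def test_exact_variant_hits_own_taxon(self):
        assert min_lv_to_references("ACGTACGTACGA", self.REFS) == (0, {"Alpha"})

    def test_tie_returns_all_argmin_taxa(self):
        refs = ReferenceSet(
            variants={"A": ["AAAATTTT"], "B": ["AAAACCCC"]},
            trim_len=8,
        )
        # equidistant: 2 substitutions from each
        seq = "AAAATTCC"
        d, taxa = min_lv_to_references(seq, refs)
        assert d == 2
        assert taxa == {"A", "B"}

    def test_matches_brute_force_scan(self, refs):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=refs.trim_len))
        d, taxa = min_lv_to_references(seq, refs)
        dists = {t: min(levenshtein(seq, v) for v in vs) for t, vs in refs.variants.items()}
        assert d == min(dists.values())
        assert taxa == {t for t, dv in dists.items() if dv == d}


class TestResolveAmbiguous:
    def test_jukes_cantor_closed_form(self):
        # 30-mer with 3 substitutions: p = 0.1, d = -0.75 ln(1 - 0.4/3)
        a = "ACGT" * 7 + "AC"
        b = _substitute(a, [0, 10, 20])
        assert jukes_cantor_distance(a, b) == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), abs=1e-9)
        assert jukes_cantor_distance(a, a) == 0.0

    def test_closer_candidate_wins(self):
        base = "ACGTACGTACGTACGTACGTACGTACGTACGT"
        refs = ReferenceSet(
            variants={"Near": [_substitute(base, [0])], "Far": [_substitute(base, [0, 8, 16])]},
            trim_len=32,
        )
        assert resolve_ambiguous(base, {"Near", "Far"}, refs) == "Near"

    def test_identical_closest_variants_stay_ambiguous(self):
        base = "ACGTACGTACGTACGT"
        refs = ReferenceSet(variants={"A": [base], "B": [base]}, trim_len=16)
        assert resolve_ambiguous(_substitute(base, [2]), {"A", "B"}, refs) == AMBIGUOUS

    def test_saturated_distance_is_infinite(self):
        assert jukes_cantor_distance("AAAAAAAA", "CCCCCCCC") == math.inf


class TestDetectChimera:
    def _distant_pair(self, refs):
        # the first two taxa are the engineered close pair; skip them
        taxa = refs.taxa
        return taxa[2], taxa[3]

    def test_constructed_bimera_called_with_parent_pair(self, refs, config):
        a, b = self._distant_pair(refs)
        va, vb = refs.variants[a][0], refs.variants[b][0]
        seq = va[:140] + vb[140:]
        result = classify_asv(seq, refs, config)
        assert result.category == "chimera"
        assert set(result.chimera.parent_pair) == {a, b}
        assert result.chimera.covered_bases == 279

    def test_scattered_substitutions_are_not_chimeric(self, refs, config):
        va = refs.variants[refs.taxa[2]][0]
        seq = _substitute(va, list(range(5, 279, 23)))  # 12 scattered subs
        d, _ = min_lv_to_references(seq, refs)
        assert d > config.error_lv_max
        assert detect_chimera(seq, refs, min_cov=266) is None
        assert classify_asv(seq, refs, config).category == "unclassified"

    def test_min_cov_larger_than_sequence_returns_none(self, refs):
        seq = refs.variants[refs.taxa[2]][0]
        assert detect_chimera(seq, refs, min_cov=500) is None

    def test_trimera_three_distinct_parents(self, refs, config):
        t = refs.taxa
        s = refs.variants[t[2]][0][:95] + refs.variants[t[3]][0][95:190] + refs.variants[t[4]][0][190:]
        result = classify_asv(s, refs, config)
        assert result.category == "chimera"
        assert result.chimera.is_trimera
        assert len({p[0] for p in result.chimera.parts}) == 3

    def test_sensitivity_on_distant_parent_bimeras(self, refs, config):
        """>= 95% of constructed two-parent chimeras are called with the right pair."""
        rng = np.random.default_rng(99)
        taxa = [t for t in refs.taxa[2:] if t.startswith("T")]
        called = 0
        n = 200
        for _ in range(n):
            a, b = rng.choice(taxa, size=2, replace=False)
            assert min(levenshtein(x, y) for x in refs.variants[a] for y in refs.variants[b]) >= 30
            bp = int(rng.integers(40, 240))
            seq = refs.variants[a][rng.integers(3)][:bp] + refs.variants[b][rng.integers(3)][bp:]
            r = classify_asv(seq, refs, config)
            if r.category == "chimera" and set(r.chimera.parent_pair) == {a, b}:
                called += 1
        assert called / n >= 0.95

    def test_no_reference_variant_self_called_chimera(self, refs, config):
        for taxon, variant in refs.iter_variants():
            r = classify_asv(variant, refs, config)
            assert r.category == "exact"
            assert r.best_taxon == taxon

    def test_lcs_index_matches_difflib_oracle(self, refs):
        import difflib

        rng = np.random.default_rng(3)
        index = LcsIndex(refs, k=20)
        a, b = refs.taxa[2], refs.taxa[4]
        for _ in range(20):
            bp = int(rng.integers(40, 240))
            seq = refs.variants[a][0][:bp] + refs.variants[b][0][bp:]
            best = index.best_match(seq)
            oracle = 0
            for _t, v in refs.iter_variants():
                sm = difflib.SequenceMatcher(None, seq, v, autojunk=False)
                m = sm.find_longest_match(0, len(seq), 0, len(v))
                oracle = max(oracle, m.size)
            assert best[0] == oracle


class TestClassifyBands:
    def test_exact_and_error_bands(self, refs, config):
        va = refs.variants[refs.taxa[3]][0]
        assert classify_asv(va, refs, config).category == "exact"
        r = classify_asv(_substitute(va, [10, 50, 100]), refs, config)
        assert r.category == "sequence_error"
        assert r.min_lv == 3
        assert r.best_taxon == refs.taxa[3]

    def test_category_fractions_partition_reads(self, experiment, config):
        table, truth = experiment
        results = classify_table(table, truth.refs, config)
        _, fractions, _ = collapse_to_species(table, results, config.accept_lv)
        totals = fractions.sum(axis=1)
        assert np.allclose(totals[table.counts.sum(axis=1) > 0], 1.0, atol=1e-9)

    def test_accepted_fraction_monotone_in_accept_lv(self, experiment, config):
        table, truth = experiment
        results = classify_table(table, truth.refs, config)
        counts = table.counts
        total = counts.to_numpy().sum()
        prev = -1.0
        for lv in range(0, 9):
            accepted = sum(
                counts[a].sum()
                for a, r in results.items()
                if r.min_lv <= lv and r.category in ("exact", "sequence_error")
            )
            frac = accepted / total
            assert frac >= prev
            prev = frac

    def test_error_band_excluded_from_species_but_reported(self, refs, config):
        import pandas as pd

        from mockdebias import AsvTable, SampleMetadata

        t3 = refs.taxa[3]
        va = refs.variants[t3][0]
        err6 = _substitute(va, [1, 40, 80, 120, 160, 200])  # LV 6: reported, not accepted
        counts = pd.DataFrame([[90, 10]], index=["s1"], columns=["good", "bad"])
        table = AsvTable(counts, {"good": va, "bad": err6}, [SampleMetadata("s1", "even_mock", "Q", "S", "q", 1e6)])
        results = classify_table(table, refs, config)
        species, fractions, flagged = collapse_to_species(table, results, config.accept_lv)
        assert species.loc["s1", t3] == pytest.approx(1.0)
        assert fractions.loc["s1", "sequence_error"] == pytest.approx(0.1)
        assert not flagged

    def test_all_unclassified_sample_flagged(self, refs, config):
        import pandas as pd

        from mockdebias import AsvTable, SampleMetadata

        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=279))
        counts = pd.DataFrame([[50]], index=["s1"], columns=["x"])
        table = AsvTable(counts, {"x": seq}, [SampleMetadata("s1", "even_mock", "Q", "S", "q", 1e6)])
        results = classify_table(table, refs, config)
        _, _, flagged = collapse_to_species(table, results, config.accept_lv)
        assert flagged == ["s1"]
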