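"""Relative abundance, 1-9 ranking, extreme codons, data-point series."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from extremocodon.abundance import (
    AbundanceResult,
    datapoint_series,
    extreme_codons,
    rank_codons,
    relative_abundance,
)
from extremocodon.significance import KsResult, SignificantCodonSet, filter_significant
from tests.conftest import paired_from_columns


def sigset_of(codons, label="toy"):
    return SignificantCodonSet(
        dataset_label=label, alpha=0.05, codons=list(codons),
        results=[KsResult(c, 0.5, 0.01, True) for c in codons],
    )


def abundance_of(codons, mean_e, mean_ne, label="toy"):
    mean_e, mean_ne = np.asarray(mean_e, float), np.asarray(mean_ne, float)
    diff = mean_e - mean_ne
    amax = float(np.max(np.abs(diff))) if len(diff) else 0.0
    return AbundanceResult(
        dataset_label=label, codons=list(codons), mean_e=mean_e, mean_ne=mean_ne,
        diff=diff, alpha_max=amax,
        beta_rel=diff / amax if amax else np.zeros_like(diff),
    )


class TestRelativeAbundance:
    def test_identical_matrices_give_all_zero_beta(self):
        paired = paired_from_columns({"AGG": [2, 4], "CAA": [1, 3]},
                                     {"AGG": [2, 4], "CAA": [1, 3]})
        res = relative_abundance(paired, sigset_of(["AGG", "CAA"]))
        assert np.all(res.diff == 0) and np.all(res.beta_rel == 0)

    def test_hand_derived_two_codon_example(self):
        # means (4,2) and (2,3) -> diffs (2,-1), alpha_max=2, beta=(1.0,-0.5)
        paired = paired_from_columns({"AGG": [4, 4], "CAA": [2, 2]},
                                     {"AGG": [2, 2], "CAA": [3, 3]})
        res = relative_abundance(paired, sigset_of(["AGG", "CAA"]))
        by = dict(zip(res.codons, res.beta_rel))
        assert res.alpha_max == pytest.approx(2.0)
        assert by["AGG"] == pytest.approx(1.0)
        assert by["CAA"] == pytest.approx(-0.5)

    def test_single_codon_self_normalizes(self):
        paired = paired_from_columns({"AGG": [5, 5]}, {"AGG": [2, 2]})
        res = relative_abundance(paired, sigset_of(["AGG"]))
        assert abs(res.beta_rel[0]) == pytest.approx(1.0)

    def test_signed_mode_matches_literal_maximum(self):
        paired = paired_from_columns({"AGG": [4, 4], "CAA": [2, 2]},
                                     {"AGG": [2, 2], "CAA": [5, 5]})
        # diffs (2, -3): absolute max 3, signed max 2
        res_abs = relative_abundance(paired, sigset_of(["AGG", "CAA"]))
        res_sgn = relative_abundance(paired, sigset_of(["AGG", "CAA"]),
                                     alpha_max_mode="signed")
        assert res_abs.alpha_max == pytest.approx(3.0)
        assert res_sgn.alpha_max == pytest.approx(2.0)
        assert res_sgn.beta_rel[1] == pytest.approx(-1.5)  # unbounded below

    def test_empty_significant_set_rejected(self, null_paired):
        paired, _ = null_paired
        with pytest.raises(ValueError, match="empty significant set"):
            relative_abundance(paired, sigset_of([]))

    def test_zero_alpha_max_warns_and_zeroes(self, caplog):
        paired = paired_from_columns({"AGG": [2, 2]}, {"AGG": [2, 2]})
        res = relative_abundance(paired, sigset_of(["AGG"]))
        assert res.alpha_max == 0.0 and res.beta_rel[0] == 0.0

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_sign_consistency_and_boundedness(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(1, 8), rng.integers(1, 10)
        codons = ["AAA", "AAC", "AAG", "AAT", "ACA", "ACC", "ACG", "ACT"][: int(n)]
        paired = paired_from_columns(
            {c: rng.uniform(0, 10, int(m)) for c in codons},
            {c: rng.uniform(0, 10, int(m)) for c in codons},
        )
        res = relative_abundance(paired, sigset_of(codons))
        assert np.all(np.abs(res.beta_rel) <= 1 + 1e-12)
        assert np.all(np.sign(res.beta_rel) == np.sign(res.diff))

    def test_positive_contributors_are_strictly_positive(self, biased_paired):
        paired, _ = biased_paired
        res = relative_abundance(paired, filter_significant(paired))
        pos = res.positive_contributors()
        by = dict(zip(res.codons, res.beta_rel))
        assert all(by[c] > 0 for c in pos)
        assert "AGG" in pos and "CAA" not in pos


class TestRankCodons:
    def test_interval_scale_by_hand(self):
        # xi = (0.5, 1.0, 1.5) -> W = (1, 5, 9) by direct evaluation
        res = abundance_of(["AAA", "CCC", "GGG"], [0.5, 1.0, 1.5], [1, 1, 1])
        table = rank_codons(res)
        assert table.W == pytest.approx([1.0, 5.0, 9.0])
        assert list(table.rank) == [1, 5, 9]
        assert table.alpha_min == 0.5 and table.beta_max == 1.5

    def test_two_codons_hit_the_endpoints(self):
        table = rank_codons(abundance_of(["AAA", "CCC"], [1.0, 2.0], [1, 1]))
        assert list(table.rank) == [1, 9]

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=20, unique=True))
    def test_scale_endpoints_and_monotonicity(self, xis):
        codons = [f"{a}{b}{c}" for a in "ACGT" for b in "ACGT" for c in "ACGT"]
        res = abundance_of(codons[: len(xis)], xis, [1.0] * len(xis))
        table = rank_codons(res)
        assert np.all((table.W >= 1 - 1e-9) & (table.W <= 9 + 1e-9))
        assert table.rank[int(np.argmax(table.xi))] == 9
        assert table.rank[int(np.argmin(table.xi))] == 1
        order = np.argsort(table.xi)
        assert np.all(np.diff(table.rank[order]) >= 0)

    def test_round_half_up(self):
        # xi = (1, 2, 3): W = (1, 5, 9); xi midway gives W = 4.5 -> rank 5
        res = abundance_of(["AAA", "CCC"], [1.0, 1 + 7.0 / 8.0], [1, 1])
        # W of second = 9; construct a 3-point case with W = 4.5 instead
        res = abundance_of(["AAA", "CCC", "GGG"], [1.0, 1.4375, 2.0], [1, 1, 1])
        table = rank_codons(res)
        assert table.W[1] == pytest.approx(4.5)
        assert table.rank[1] == 5

    def test_all_equal_ratios_collapse_to_rank_5(self, caplog):
        table = rank_codons(abundance_of(["AAA", "CCC"], [2.0, 2.0], [1, 1]))
        assert list(table.rank) == [5, 5]

    def test_zero_denominator_uses_pseudocount_and_flags(self):
        res = abundance_of(["AAA", "CCC"], [2.0, 1.0], [0.0, 1.0])
        table = rank_codons(res)
        assert table.pseudocount_codons == ["AAA"]
        assert np.isfinite(table.xi).all()
        # pseudocount = half the smallest nonzero mean (0.5) -> xi = 4
        assert table.xi[0] == pytest.approx(2.0 / 0.5)


class TestExtremeCodons:
    def test_recovers_injected_extremes(self, biased_paired):
        paired, _ = biased_paired
        table = rank_codons(relative_abundance(paired, filter_significant(paired)))
        assert extreme_codons(table) == ("AGG", "CAA")

    def test_single_codon_table(self):
        table = rank_codons(abundance_of(["AGG"], [2.0], [1.0]))
        assert extreme_codons(table) == ("AGG", "AGG")

    def test_lexicographic_tie_break(self):
        table = rank_codons(
            abundance_of(["AGG", "AGA", "CAA"], [2.0, 2.0, 1.0], [1, 1, 1]))
        highest, lowest = extreme_codons(table)
        assert highest == "AGA"  # AGA < AGG lexicographically
        assert lowest == "CAA"


class TestDatapointSeries:
    def test_normalized_by_global_maximum(self):
        paired = paired_from_columns({"AGG": [2, 4, 8]}, {"AGG": [1, 2, 4]})
        series = datapoint_series(paired, "AGG")
        assert series.values_e == pytest.approx([0.25, 0.5, 1.0])
        assert series.values_ne == pytest.approx([0.125, 0.25, 0.5])

    def test_all_equal_positive_values_map_to_one(self):
        paired = paired_from_columns({"AGG": [3, 3]}, {"AGG": [3, 3]})
        series = datapoint_series(paired, "AGG")
        assert np.all(series.values_e == 1.0) and np.all(series.values_ne == 1.0)

    def test_all_zero_series_stays_zero(self, caplog):
        paired = paired_from_columns({"AGG": [1, 1]}, {"AGG": [1, 1]})
        series = datapoint_series(paired, "TTT")
        assert np.all(series.values_e == 0) and np.all(series.values_ne == 0)

    def test_output_always_within_unit_interval(self, biased_paired):
        paired, _ = biased_paired
        for codon in ("AGG", "CAA", "ATG"):
            s = datapoint_series(paired, codon)
            for v in (s.values_e, s.values_ne):
                assert np.all((v >= 0) & (v <= 1))
            assert max(s.values_e.max(), s.values_ne.max()) == pytest.approx(1.0)
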