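"""Screen normalization, ranking, toxicity classes and composition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from seedtox.screen import (
    DegenerateControlError,
    MissingControlError,
    classify_toxicity,
    normalize_screen,
    nucleotide_composition,
    rank_seeds,
    screen_correlation,
)

from conftest import make_wells


class TestNormalize:
    def test_replicates_averaged_after_set_normalization(self, simple_wells):
        # hand arithmetic: (250 + 350) / 2 / 1000 * 100 = 30%
        m = normalize_screen(simple_wells)
        assert m.viability.loc["AAAAAA", "L1"] == pytest.approx(30.0)

    def test_identity_when_all_wells_equal_control_mean(self):
        rows = [("CTRL", "L1", "S1", 1, 800.0, True, "siNT1")]
        for i, seed in enumerate(["AAAAAA", "CCCCCC", "GGGGGG"]):
            rows.append((seed, "L1", "S1", 1, 800.0, False, ""))
        m = normalize_screen(make_wells(rows))
        assert np.allclose(m.viability["L1"].to_numpy(), 100.0)

    def test_control_mean_maps_to_100_per_set(self):
        rows = [
            ("CTRL", "L1", "S1", 1, 900.0, True, "siNT1"),
            ("CTRL", "L1", "S1", 2, 1100.0, True, "siNT1"),
            ("CTRL", "L1", "S2", 1, 50.0, True, "siNT1"),
            ("AAAAAA", "L1", "S1", 1, 500.0, False, ""),
            ("CCCCCC", "L1", "S2", 1, 25.0, False, ""),
        ]
        m = normalize_screen(make_wells(rows))
        for v in m.provenance["control_viability_mean_by_set"].values():
            assert v == pytest.approx(100.0, abs=1e-9)
        # set effect cancels: both seeds at 50% of their own control
        assert m.viability.loc["AAAAAA", "L1"] == pytest.approx(50.0)
        assert m.viability.loc["CCCCCC", "L1"] == pytest.approx(50.0)

    def test_missing_control_names_the_set(self):
        rows = [
            ("CTRL", "L1", "S1", 1, 1000.0, True, "siNT1"),
            ("AAAAAA", "L1", "S1", 1, 500.0, False, ""),
            ("CCCCCC", "L1", "S2", 1, 400.0, False, ""),
        ]
        with pytest.raises(MissingControlError, match="S2"):
            normalize_screen(make_wells(rows))

    def test_zero_control_mean_is_degenerate(self):
        rows = [
            ("CTRL", "L1", "S1", 1, 0.0, True, "siNT1"),
            ("AAAAAA", "L1", "S1", 1, 500.0, False, ""),
        ]
        with pytest.raises(DegenerateControlError):
            normalize_screen(make_wells(rows))


class TestRanking:
    @staticmethod
    def _matrix(values):
        rows = [("CTRL", "L1", "S1", 1, 1000.0, True, "siNT1")]
        rows += [(s, "L1", "S1", 1, v * 10, False, "") for s, v in values.items()]
        return normalize_screen(make_wells(rows))

    def test_single_seed_gets_rank_one(self):
        r = rank_seeds(self._matrix({"AAAAAA": 42.0}))
        assert r.table["rank"].tolist() == [1]

    def test_sorted_most_toxic_first_with_lexicographic_ties(self):
        r = rank_seeds(self._matrix({"UUUUUU": 20.0, "AAAAAA": 20.0, "CCCCCC": 5.0}))
        assert r.seeds == ["CCCCCC", "AAAAAA", "UUUUUU"]
        assert r.table["rank"].tolist() == [1, 2, 3]

    def test_ranking_invariant_under_row_order(self):
        vals = {"ACGUAC": 30.0, "GGGGGG": 5.0, "UUUUUU": 90.0, "CCCCCC": 30.0}
        m = self._matrix(vals)
        shuffled = m.viability.sample(frac=1, random_state=0)
        m2 = type(m)(shuffled, m.provenance)
        assert rank_seeds(m).seeds == rank_seeds(m2).seeds

    def test_unknown_cell_line_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            rank_seeds(self._matrix({"AAAAAA": 10.0}), ["NOPE"])

    def test_ranks_are_permutation(self):
        vals = {s: v for s, v in zip(
            ["AAAAAA", "ACGUAC", "CCCCCC", "GGGGGG", "UUUUUU"],
            [55.0, 13.0, 77.0, 2.0, 101.0])}
        r = rank_seeds(self._matrix(vals))
        assert sorted(r.table["rank"]) == list(range(1, 6))


class TestToxicityClasses:
    @pytest.mark.parametrize(
        "viability,expected",
        [
            (9.9, "highly_toxic"),
            (10.0, "highly_toxic"),
            (10.1, "moderately_toxic"),
            (50.0, "moderately_toxic"),
            (50.1, "non_toxic"),
            (100.0, "non_toxic"),
        ],
    )
    def test_boundaries(self, viability, expected):
        assert classify_toxicity(viability) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_toxicity(-1.0)


class TestCorrelation:
    def test_perfect_and_inverse(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert screen_correlation(x, x)[0] == pytest.approx(1.0)
        r, _ = screen_correlation(x, [-v + 10 for v in x])
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        r, _ = screen_correlation(x, y)
        xm, ym = x - x.mean(), y - y.mean()
        r_hand = (xm * ym).sum() / (
            np.sqrt((xm**2).sum()) * np.sqrt((ym**2).sum())
        )
        assert r == pytest.approx(r_hand, abs=1e-12)

    def test_constant_vector_undefined(self):
        with pytest.raises(ValueError):
            screen_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestComposition:
    def test_single_seed(self):
        pfm = nucleotide_composition(["GGGGGC"])
        assert pfm.counts.loc[6, "C"] == 1
        assert pfm.counts.loc[6, "G"] == 0
        for pos in range(1, 6):
            assert pfm.counts.loc[pos, "G"] == 1

    def test_uniform_symmetry(self):
        pfm = nucleotide_composition(["AAAAAA", "CCCCCC", "GGGGGG", "UUUUUU"])
        assert (pfm.counts.to_numpy() == 1).all()
        assert np.allclose(pfm.frequencies.sum(axis=1), 1.0)

    def test_invalid_letter_names_seed(self):
        with pytest.raises(ValueError, match="GGXGGG"):
            nucleotide_composition(["GGXGGG"])

    @settings(max_examples=30, derandomize=True)
    @given(
        hst.lists(
            hst.text(alphabet="ACGU", min_size=6, max_size=6),
            min_size=1,
            max_size=60,
        )
    )
    def test_column_sums_conserve_group_size(self, seeds):
        pfm = nucleotide_composition(seeds)
        assert (pfm.counts.sum(axis=1) == len(seeds)).all()
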