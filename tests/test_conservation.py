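import math
from io import StringIO

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protascan import (
    Alignment,
    BackgroundFrequencies,
    column_profile,
    conservation_threshold,
    gap_weighted_score,
    load_background,
    mask_leading_met,
    relative_entropy,
    scan_alignment,
)
from _oracles import brute_force_column_scores

AA20 = "ACDEFGHIKLMNPQRSTVWY"
UNIFORM = BackgroundFrequencies({a: 0.05 for a in AA20}, "uniform")


def aln_from_columns(*columns):
    """Build an alignment whose i-th column is the i-th string (rows read down)."""
    n_rows = len(columns[0])
    rows = tuple("".join(col[i] for col in columns) for i in range(n_rows))
    return Alignment(tuple(f"r{i}" for i in range(n_rows)), rows)


class TestBackground:
    def test_bundled_table_covers_extended_alphabet(self, bg):
        assert set(bg.q) == set(AA20) | {"B", "Z", "X"}
        assert all(f > 0 for f in bg.q.values())
        assert bg["B"] == pytest.approx(bg["D"] + bg["N"])
        assert bg["Z"] == pytest.approx(bg["E"] + bg["Q"])
        assert bg["X"] == 1.0

    def test_missing_residue_rejected(self):
        table = "\n".join(f"{a}\t0.05" for a in AA20 if a != "W")
        with pytest.raises(ValueError, match="W"):
            load_background(StringIO(table))

    def test_uniform_null_background_accepted(self):
        table = "\n".join(f"{a}\t0.05" for a in AA20)
        bg = load_background(StringIO(table))
        assert bg["A"] == 0.05

    def test_non_positive_frequency_rejected(self):
        q = {a: 0.05 for a in AA20}
        q["A"] = 0.0
        q["C"] = 0.10
        with pytest.raises(ValueError, match="non-positive"):
            BackgroundFrequencies(q)


class TestMasking:
    @pytest.mark.parametrize(
        "row,masked_col",
        [("MARYR", 1), ("--MAR", 3), ("M----", 1)],
    )
    def test_initiator_met_masked(self, row, masked_col):
        masked = mask_leading_met(Alignment(("x",), (row,)))
        assert masked.masked == frozenset({(0, masked_col)})

    def test_row_without_initiator_met_untouched(self):
        masked = mask_leading_met(Alignment(("x",), ("ARMAR",)))
        assert masked.masked == frozenset()


class TestColumnProfile:
    def test_pure_gapless_column(self):
        profile = column_profile(aln_from_columns("CCCC"), 1)
        assert profile.p == {"C": 1.0}
        assert profile.nongap_fraction == 1.0

    def test_half_gapped_column(self):
        profile = column_profile(aln_from_columns("CC--"), 1)
        assert profile.p == {"C": 1.0}
        assert profile.nongap_fraction == 0.5

    def test_masked_met_counts_as_gap(self):
        # rows: "C", "Y", "-", "M" -- the M is each row's first residue, so masked
        aln = aln_from_columns("CY-M")
        profile = column_profile(mask_leading_met(aln), 1)
        assert profile.p == {"C": 0.5, "Y": 0.5}
        assert profile.nongap_fraction == 0.5

    def test_all_gap_column_is_valid(self):
        profile = column_profile(aln_from_columns("AA", "--"), 2)
        assert profile.p == {}
        assert profile.nongap_fraction == 0.0


class TestScores:
    def test_zero_when_column_matches_background(self):
        # one row per residue: P is uniform over the 20 aa, equal to UNIFORM Q
        profile = column_profile(aln_from_columns(AA20), 1)
        assert relative_entropy(profile, UNIFORM) == pytest.approx(0.0, abs=1e-12)

    def test_pure_arginine_column_scores_the_printed_threshold(self, bg):
        profile = column_profile(aln_from_columns("RRRR"), 1)
        assert relative_entropy(profile, bg) == pytest.approx(4.1354, abs=5e-4)

    def test_pure_cysteine_under_uniform_background(self):
        profile = column_profile(aln_from_columns("CCCC"), 1)
        assert relative_entropy(profile, UNIFORM) == pytest.approx(math.log2(20))

    def test_empty_profile_is_an_error(self, bg):
        profile = column_profile(aln_from_columns("AA", "--"), 2)
        with pytest.raises(ValueError):
            relative_entropy(profile, bg)

    def test_gap_weight_halves_the_score(self, bg):
        gapless = column_profile(aln_from_columns("RRRR"), 1)
        half = column_profile(aln_from_columns("RR--"), 1)
        assert gap_weighted_score(gapless, bg) == pytest.approx(relative_entropy(gapless, bg))
        assert gap_weighted_score(half, bg) == pytest.approx(
            0.5 * relative_entropy(gapless, bg)
        )

    def test_all_gap_column_scores_zero(self, bg):
        assert gap_weighted_score(column_profile(aln_from_columns("AA", "--"), 2), bg) == 0.0


class TestThreshold:
    def test_bundled_background_gives_printed_value(self, bg):
        assert conservation_threshold(bg) == pytest.approx(4.1354, abs=5e-4)

    def test_uniform_background_symmetric_across_residues(self):
        assert conservation_threshold(UNIFORM, "C") == pytest.approx(math.log2(20))
        assert conservation_threshold(UNIFORM, "W") == pytest.approx(math.log2(20))

    def test_unknown_residue_rejected(self, bg):
        with pytest.raises(KeyError):
            conservation_threshold(bg, "J")

    @pytest.mark.parametrize("q_lo,q_hi", [(0.01, 0.02), (0.02, 0.05), (0.05, 0.2)])
    def test_strictly_decreasing_in_background_frequency(self, q_lo, q_hi):
        def bg_with_r(q_r):
            q = {a: (1 - q_r) / 19 for a in AA20 if a != "R"}
            q["R"] = q_r
            return BackgroundFrequencies(q)

        assert conservation_threshold(bg_with_r(q_lo)) > conservation_threshold(bg_with_r(q_hi))


class TestScanAlignment:
    def test_score_equal_to_threshold_is_not_conserved(self, bg):
        # a gapless all-arginine column scores exactly the threshold
        result = scan_alignment(aln_from_columns("RRRR", "CCCC"), bg)
        assert result[1].g_w == result.threshold
        assert not result[1].conserved
        assert result[2].conserved

    def test_planted_cysteine_column_is_called(self, bg):
        rng = np.random.default_rng(7)
        cols = ["".join(rng.choice(list("RSKGA"), 20)) for _ in range(10)]
        cols[4] = "C" * 20
        result = scan_alignment(aln_from_columns(*cols), bg)
        assert result.conserved_positions() == [5]
        assert result[5].majority_symbol == "C"
        assert result[5].purity == 1.0

    def test_background_sampled_columns_are_never_called(self, bg):
        rng = np.random.default_rng(11)
        symbols = sorted(set(bg.q) - {"B", "Z", "X"})
        probs = np.array([bg[a] for a in symbols])
        probs /= probs.sum()
        rows = ["".join(rng.choice(symbols, 100, p=probs)) for _ in range(50)]
        aln = Alignment(tuple(f"r{i}" for i in range(50)), tuple(rows))
        assert scan_alignment(aln, bg).conserved_positions() == []

    def test_agrees_with_brute_force_oracle(self, bg):
        rng = np.random.default_rng(3)
        alphabet = list(AA20 + "BZX" + "---")
        for _ in range(20):
            rows = tuple("".join(rng.choice(alphabet, 30)) for _ in range(10))
            aln = Alignment(tuple(f"r{i}" for i in range(10)), rows)
            result = scan_alignment(aln, bg)
            expected = brute_force_column_scores(
                aln.row_ids, aln.rows, bg.q, result.threshold
            )
            for score, (d_kl, g_w, conserved) in zip(result.columns, expected):
                assert score.d_kl == pytest.approx(d_kl, abs=1e-9)
                assert score.g_w == pytest.approx(g_w, abs=1e-9)
                assert score.conserved == conserved

    def test_conserved_positions_sorted_by_descending_score(self, bg):
        result = scan_alignment(aln_from_columns("CCCC", "RRRR", "WWWW", "CC-C"), bg)
        positions = result.conserved_positions()
        scores = [result[c].g_w for c in positions]
        assert scores == sorted(scores, reverse=True)
        assert set(positions) <= {1, 3, 4}

    def test_row_order_permutation_does_not_change_scores(self, bg):
        aln = aln_from_columns("CYCA", "RRRR", "AC-G")
        flipped = Alignment(tuple(reversed(aln.row_ids)), tuple(reversed(aln.rows)))
        a = [c.g_w for c in scan_alignment(aln, bg).columns]
        b = [c.g_w for c in scan_alignment(flipped, bg).columns]
        assert a == pytest.approx(b, abs=1e-12)


@given(
    st.lists(
        st.text(alphabet=AA20 + "-", min_size=8, max_size=8).filter(
            lambda s: s.replace("-", "")
        ),
        min_size=2,
        max_size=12,
    )
)
@settings(max_examples=60, deadline=None)
def test_score_invariants_hold_for_arbitrary_columns(bg_rows):
    """d_kl >= 0 and 0 <= g_w <= d_kl, with equality only for gapless columns."""
    bg = BackgroundFrequencies({a: 0.05 for a in AA20})
    aln = Alignment(tuple(f"r{i}" for i in range(len(bg_rows))), tuple(bg_rows))
    for score in scan_alignment(aln, bg, apply_leading_met_mask=False).columns:
        assert score.d_kl >= -1e-12
        assert -1e-12 <= score.g_w <= score.d_kl + 1e-12
        if score.gap_weight == 1.0:
            assert score.g_w == pytest.approx(score.d_kl)
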