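"""Section summaries, within-leaf permutation tests, letter displays."""

import numpy as np
import pandas as pd
import pytest

from stomapattern import (compare_levels, letter_display,
                          paired_permutation_test, summarize_sections)


def make_stats_df(cells, n_leaves=16, rng=None):
    """Per-window stats frame from {(species, layer, position): mean_sd}."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for (sp, layer, pos), mean_sd in cells.items():
        for leaf in range(1, n_leaves + 1):
            sd = mean_sd * (1 + 0.03 * rng.standard_normal())
            rows.append({"species": sp, "leaf_id": f"leaf{leaf:02d}",
                         "layer": layer, "position": pos,
                         "sd": sd, "mnnd": 500 / np.sqrt(sd),
                         "sai": 1.2 + 0.02 * rng.standard_normal()})
    return pd.DataFrame(rows)


class TestSummarizeSections:
    def test_constant_cell_has_zero_cv(self):
        df = pd.DataFrame({
            "species": "A", "leaf_id": [f"l{i}" for i in range(3)],
            "layer": 1, "position": 1,
            "sd": [10.0, 10.0, 10.0], "mnnd": 30.0, "sai": 1.2,
        })
        out = summarize_sections(df)
        row = out[(out.metric == "sd")].iloc[0]
        assert row["mean"] == pytest.approx(10.0)
        assert row["cv_pct"] == 0.0

    def test_two_value_cell_cv(self):
        # sample SD of (8, 12) is 2√2, so CV = 100·2√2/10 ≈ 28.28%
        df = pd.DataFrame({
            "species": "A", "leaf_id": ["l1", "l2"],
            "layer": 1, "position": 1,
            "sd": [8.0, 12.0], "mnnd": 30.0, "sai": 1.2,
        })
        row = summarize_sections(df)
        sd_row = row[row.metric == "sd"].iloc[0]
        assert sd_row["mean"] == pytest.approx(10.0)
        assert sd_row["median"] == pytest.approx(10.0)
        assert sd_row["cv_pct"] == pytest.approx(28.28)

    def test_duplicate_section_records_rejected(self):
        df = pd.DataFrame({
            "species": "A", "leaf_id": "l1", "layer": 1, "position": 1,
            "sd": [8.0, 12.0], "mnnd": 30.0, "sai": 1.2,
        })
        with pytest.raises(ValueError, match="duplicate"):
            summarize_sections(df)

    def test_missing_metadata_rejected(self):
        df = pd.DataFrame({
            "species": ["A", None], "leaf_id": ["l1", "l2"],
            "layer": 1, "position": 1,
            "sd": [8.0, 12.0], "mnnd": 30.0, "sai": 1.2,
        })
        with pytest.raises(ValueError, match="missing metadata"):
            summarize_sections(df)

    def test_generator_ordering_recovered(self):
        # midrib (pos 1) above margin (pos 2) in every layer of the input
        cells = {("A", l, p): 300 - 40 * (l - 1) - 80 * (p - 1)
                 for l in (1, 2, 3) for p in (1, 2)}
        out = summarize_sections(make_stats_df(cells))
        sd = out[out.metric == "sd"].set_index(["layer", "position"])
        for layer in (1, 2, 3):
            assert (sd.loc[(layer, 1), "mean"]
                    > sd.loc[(layer, 2), "mean"])


class TestPairedPermutationTest:
    def test_identical_samples_give_p_one(self):
        a = np.arange(10.0)
        res = paired_permutation_test(a, a.copy(), n_perm=999, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_strong_one_sided_differences_are_significant(self):
        # all 10 paired differences strictly positive and large: the only
        # sign patterns with |T| as extreme are all-plus and all-minus,
        # so the exact p-value is 2/2^10
        a = np.full(10, 5.0) + np.arange(10) * 0.01
        b = np.zeros(10)
        res = paired_permutation_test(a, b, method="exact")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 1024)
        assert res.p_value < 0.05

    def test_exact_enumeration_matches_monte_carlo(self, rng):
        a = rng.normal(0.4, 1.0, 10)
        b = rng.normal(0.0, 1.0, 10)
        exact = paired_permutation_test(a, b, method="exact")
        mc = paired_permutation_test(a, b, n_perm=40000, seed=1,
                                     method="monte-carlo")
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_invariant_to_common_constant(self, rng):
        a = rng.normal(1, 1, 12)
        b = rng.normal(0, 1, 12)
        r1 = paired_permutation_test(a, b, n_perm=999, seed=3)
        r2 = paired_permutation_test(a + 100.0, b + 100.0, n_perm=999, seed=3)
        assert r1.p_value == r2.p_value

    def test_requires_six_pairs(self):
        with pytest.raises(ValueError, match="6"):
            paired_permutation_test([1, 2, 3], [1, 2, 3])

    def test_type_one_error_calibrated(self, rng):
        # both cells from one common distribution: rejection rate ≈ α
        n_sim, alpha = 600, 0.05
        rejections = 0
        for k in range(n_sim):
            a = rng.normal(0, 1, 16)
            b = rng.normal(0, 1, 16)
            res = paired_permutation_test(a, b, n_perm=499, seed=k)
            rejections += res.p_value <= alpha
        rate = rejections / n_sim
        assert 0.025 <= rate <= 0.075


class TestLetterDisplay:
    def test_transitive_chain_shares_letter(self):
        # A≈B and B≈C non-significant groups all three together, even
        # though A vs C alone is significant (documented convention)
        letters = letter_display(
            ["A", "B", "C"], {"A": 3.0, "B": 2.0, "C": 1.0},
            {("A", "B"): 0.30, ("B", "C"): 0.40, ("A", "C"): 0.001},
        )
        assert letters["A"] == letters["B"] == letters["C"]

    def test_separated_groups_get_distinct_letters_by_mean(self):
        letters = letter_display(
            ["lo", "hi", "mid"], {"lo": 1.0, "hi": 9.0, "mid": 5.0},
            {("lo", "hi"): 0.001, ("lo", "mid"): 0.002, ("hi", "mid"): 0.003},
        )
        assert letters["hi"] == "a"
        assert letters["mid"] == "b"
        assert letters["lo"] == "c"


class TestCompareLevels:
    def test_detects_position_effect_and_letters(self):
        cells = {("A", l, p): (300.0 if p == 1 else 200.0)
                 for l in (1, 2) for p in (1, 2)}
        df = make_stats_df(cells)
        pairs, letters = compare_levels(
            df, "sd", "position", fixed={"species": "A", "layer": 1},
            n_perm=999, seed=0)
        assert pairs["p_value"].iloc[0] < 0.05
        assert letters[1] == "a" and letters[2] == "b"

    def test_missing_leaf_is_named(self):
        cells = {("A", 1, 1): 300.0, ("A", 1, 2): 200.0}
        df = make_stats_df(cells)
        df = df.drop(df[(df.leaf_id == "leaf03") & (df.position == 2)].index)
        with pytest.raises(ValueError, match="leaf03"):
            compare_levels(df, "sd", "position",
                           fixed={"species": "A", "layer": 1}, seed=0)

    def test_holm_adjustment_is_monotone(self):
        cells = {("A", l, 1): 300.0 - 30 * l for l in (1, 2, 3)}
        df = make_stats_df(cells)
        plain, _ = compare_levels(df, "sd", "layer",
                                  fixed={"species": "A", "position": 1},
                                  n_perm=999, seed=0)
        holm, _ = compare_levels(df, "sd", "layer",
                                 fixed={"species": "A", "position": 1},
                                 n_perm=999, seed=0, adjust="holm")
        assert np.all(holm["p_value_adj"].to_numpy()
                      >= plain["p_value"].to_numpy() - 1e-12)
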