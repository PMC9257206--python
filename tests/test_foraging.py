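"""Foraging bouts: transition counting, ethological RI, constancy, G-test."""

import math
import statistics
from collections import Counter

import pytest
from scipy.stats import power_divergence

from ricascade import (EmptyInputError, ForagingBout, NotEstimable,
                       SchemaError, TransitionTable, UndefinedIndexError,
                       bout_constancy, count_transitions, ethological_ri,
                       g_test_transitions, pollinator_constancy_summary,
                       ri_from_counts)
from ricascade.foraging import read_bouts_csv
from ricascade.synthetic_data import ForagingConfig, simulate_bouts


def bout(visits, bout_id="b1", pollinator="moth"):
    return ForagingBout(bout_id=bout_id, pollinator=pollinator,
                        visits=tuple(visits))


class TestCountTransitions:
    def test_single_species_bout(self):
        table = count_transitions([bout("aaa")], "a", "b")
        assert (table.n_aa, table.n_bb, table.n_ab, table.n_ba) == (2, 0, 0, 0)

    def test_single_visit_bout_contributes_nothing(self):
        table = count_transitions([bout("a"), bout("ab", "b2")], "a", "b")
        assert table.total == 1

    def test_totals_equal_visits_minus_bouts(self, rng):
        bouts = simulate_bouts(ForagingConfig("a", "b", n_bouts=100, kappa=0.6),
                               rng)
        table = count_transitions(bouts, "a", "b")
        assert table.total == sum(len(b.visits) - 1 for b in bouts)

    def test_matches_brute_force_pair_enumeration(self, rng):
        bouts = simulate_bouts(ForagingConfig("a", "b", n_bouts=100, kappa=0.3),
                               rng)
        table = count_transitions(bouts, "a", "b")
        pairs = Counter()
        for b in bouts:
            for prev, nxt in zip(b.visits, b.visits[1:]):
                pairs[prev + nxt] += 1
        assert (table.n_aa, table.n_bb, table.n_ab, table.n_ba) == (
            pairs["aa"], pairs["bb"], pairs["ab"], pairs["ba"])

    def test_unknown_species_names_bout(self):
        with pytest.raises(SchemaError, match="b7"):
            count_transitions([bout("axb", "b7")], "a", "b")

    def test_empty_input(self):
        with pytest.raises(EmptyInputError):
            count_transitions([], "a", "b")


class TestEthologicalRI:
    def test_reference_array_values(self, reference_tables):
        lim_dav = reference_tables["lim_dav"]
        assert ethological_ri(lim_dav, "lim") == pytest.approx(0.882, abs=5e-4)
        assert ethological_ri(lim_dav, "dav") == pytest.approx(0.647, abs=5e-4)
        lim_del = reference_tables["lim_del"]
        assert ethological_ri(lim_del, "lim") == pytest.approx(0.667, abs=5e-4)
        assert ethological_ri(lim_del, "del") == pytest.approx(0.733, abs=5e-4)

    def test_orientation_is_transitions_into_focal(self):
        # 16 a->a, 1 b->a: focal a sees C=16, H=1
        table = TransitionTable("a", "b", n_aa=16, n_bb=14, n_ab=3, n_ba=1)
        assert ethological_ri(table, "a") == ri_from_counts(H=1, C=16)

    def test_segmentation_invariance(self):
        whole = count_transitions([bout("aabab")], "a", "b")
        split = count_transitions([bout("aab", "b1"), bout("bab", "b2")],
                                  "a", "b")
        assert (whole.n_aa, whole.n_ab, whole.n_ba) == \
            (split.n_aa, split.n_ab, split.n_ba)
        assert ethological_ri(whole, "a") == ethological_ri(split, "a")

    def test_no_transitions_into_focal(self):
        table = TransitionTable("a", "b", n_aa=0, n_bb=5, n_ab=2, n_ba=0)
        with pytest.raises(UndefinedIndexError):
            ethological_ri(table, "a")


class TestBoutConstancy:
    def test_all_conspecific_bout(self):
        assert bout_constancy(bout("aaaa"), "a", "b") == 1.0

    def test_alternating_bout(self):
        assert bout_constancy(bout("abab"), "a", "b") == pytest.approx(-1.0)

    def test_mixed_bout_hand_value(self):
        # aabb: c=2/3, p=1/2, e=1/2 -> CI = (1/6)/(1/2) = 1/3
        assert bout_constancy(bout("aabb"), "a", "b") == pytest.approx(1 / 3)

    def test_single_visit_not_estimable(self):
        with pytest.raises(NotEstimable):
            bout_constancy(bout("a"), "a", "b")


class TestConstancySummary:
    def test_all_conspecific_pollinator(self):
        bouts = [bout("aaaa", f"b{i}", "Trichoplusia intermixta")
                 for i in range(4)]
        summary = pollinator_constancy_summary(
            bouts, "Trichoplusia intermixta", "a", "b")
        assert summary["mean_CI"] == pytest.approx(1.0)
        assert summary["sd_CI"] == 0.0
        assert summary["n_bouts"] == 4

    def test_single_bout_sd_reported_zero_with_n_flag(self):
        summary = pollinator_constancy_summary([bout("aab")], "moth", "a", "b")
        assert summary["sd_CI"] == 0.0 and summary["n_bouts"] == 1

    def test_matches_direct_mean_sd(self, rng):
        bouts = simulate_bouts(ForagingConfig("a", "b", n_bouts=40, kappa=0.5),
                               rng)
        cis = [bout_constancy(b, "a", "b") for b in bouts
               if len(b.visits) >= 2]
        summary = pollinator_constancy_summary(bouts, "sim_moth", "a", "b")
        assert summary["mean_CI"] == pytest.approx(statistics.fmean(cis))
        assert summary["sd_CI"] == pytest.approx(statistics.stdev(cis))

    def test_no_estimable_bouts(self):
        with pytest.raises(NotEstimable):
            pollinator_constancy_summary([bout("a")], "moth", "a", "b")


class TestGTest:
    @pytest.mark.parametrize("intra, inter, g_expected", [
        (30, 4, 22.50),
        (23, 4, 14.78),
    ])
    def test_reference_values(self, intra, inter, g_expected):
        g, df, p = g_test_transitions(intra, inter)
        assert g == pytest.approx(g_expected, abs=5e-3)
        assert df == 1
        assert p < 0.001

    def test_equal_counts(self):
        g, _, p = g_test_transitions(12, 12)
        assert g == 0.0 and p == pytest.approx(1.0)

    def test_zero_cell_contributes_zero(self):
        g, _, _ = g_test_transitions(5, 0)
        assert g == pytest.approx(2 * 5 * math.log(2.0))

    def test_label_swap_invariance(self):
        assert g_test_transitions(23, 4)[0] == g_test_transitions(4, 23)[0]

    def test_agrees_with_brute_force_and_scipy(self, rng):
        for _ in range(1000):
            o1, o2 = (int(v) for v in rng.integers(1, 500, size=2))
            g, _, p = g_test_transitions(o1, o2)
            e = (o1 + o2) / 2
            brute = 2 * (o1 * math.log(o1 / e) + o2 * math.log(o2 / e))
            assert g == pytest.approx(brute, abs=1e-10)
            ref = power_divergence([o1, o2], lambda_="log-likelihood")
            assert g == pytest.approx(float(ref.statistic), abs=1e-10)
            assert p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_both_zero(self):
        with pytest.raises(EmptyInputError):
            g_test_transitions(0, 0)


class TestCSVIngestion:
    def test_visit_rows_round_trip(self, tmp_path):
        path = tmp_path / "bouts.csv"
        path.write_text(
            "bout_id,pollinator,visit_order,plant_species\n"
            "b1,moth,2,b\nb1,moth,1,a\nb2,moth,1,a\n"
        )
        bouts = read_bouts_csv(path)
        assert bouts[0].visits == ("a", "b")   # ordered by visit_order
        assert bouts[1].visits == ("a",)

    def test_conflicting_pollinator_rejected(self, tmp_path):
        path = tmp_path / "bouts.csv"
        path.write_text(
            "bout_id,pollinator,visit_order,plant_species\n"
            "b1,moth1,1,a\nb1,moth2,2,b\n"
        )
        with pytest.raises(SchemaError):
            read_bouts_csv(path)
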