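"""Competition scoring and shuffled-label permutation machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from adslkit import behavior
from adslkit.behavior import HADSL, WT

from conftest import events_frame, roster_frame


class TestFirstNProportion:
    def test_all_hadsl_gives_one(self, small_roster):
        ev = events_frame([("c1", 1, float(i), "h1", 1, 3) for i in range(10)])
        out = behavior.first_n_proportion(ev, small_roster, K=10)
        assert out.loc[0, "proportion_hadsl"] == 1.0

    def test_alternating_gives_half(self, small_roster, alternating_events):
        out = behavior.first_n_proportion(alternating_events, small_roster, K=10)
        assert out.loc[0, "proportion_hadsl"] == 0.5
        assert out.loc[0, "n_counted"] == 10

    def test_short_day_keeps_n_counted(self, small_roster):
        # 7 visits only: 5 hAdsl + 2 WT among them, K = 10
        animals = ["h1", "h2", "h1", "w1", "h2", "w2", "h1"]
        ev = events_frame(
            [("c1", 1, float(i), a, 1, 0) for i, a in enumerate(animals)]
        )
        out = behavior.first_n_proportion(ev, small_roster, K=10)
        assert out.loc[0, "n_counted"] == 7
        assert out.loc[0, "proportion_hadsl"] == pytest.approx(5 / 7)

    def test_onset_and_corner_eligibility(self, small_roster):
        ev = events_frame(
            [
                ("c1", 1, 5.0, "w1", 1, 0),   # before onset
                ("c1", 1, 20.0, "w2", 3, 0),  # unrewarded corner
                ("c1", 1, 30.0, "h1", 1, 0),
                ("c1", 1, 40.0, "w1", 2, 0),
            ]
        )
        out = behavior.first_n_proportion(
            ev, small_roster, K=10, onset=10.0, rewarded_corners={1, 2}
        )
        assert out.loc[0, "n_counted"] == 2
        assert out.loc[0, "proportion_hadsl"] == 0.5

    def test_unknown_animal_raises(self, small_roster):
        ev = events_frame([("c1", 1, 0.0, "ghost", 1, 0)])
        with pytest.raises(KeyError, match="ghost"):
            behavior.first_n_proportion(ev, small_roster, K=5)

    def test_single_genotype_cage_excluded_with_warning(self):
        roster = roster_frame(
            [("w1", WT, "F", "c1"), ("w2", WT, "F", "c1")]
        )
        ev = events_frame([("c1", 1, 0.0, "w1", 1, 0)])
        with pytest.warns(UserWarning, match="c1"):
            out = behavior.first_n_proportion(ev, roster, K=5)
        assert out.empty

    def test_proportions_of_both_genotypes_sum_to_one(self, small_roster):
        rng = np.random.default_rng(7)
        animals = rng.choice(["h1", "h2", "w1", "w2"], size=30)
        ev = events_frame(
            [("c1", 1 + i // 10, float(i), a, 1, 0) for i, a in enumerate(animals)]
        )
        out = behavior.first_n_proportion(ev, small_roster, K=10)
        # WT proportion is the complement within the counted visits
        wt_prop = 1 - out["proportion_hadsl"]
        assert np.allclose(
            out["proportion_hadsl"] + wt_prop, 1.0
        ) and (out["n_counted"] > 0).all()


def exhaustive_permutation_p(counts_by_cage, labels_by_cage, n_counted_by_cage):
    """Brute-force oracle: the exact two-tailed p over all within-cage relabelings.

    Enumerates every assignment of hAdsl labels within each cage
    (label counts preserved), computes the mean-across-cages
    proportion, and applies the same distance-from-the-mean rule as
    the Monte-Carlo test, without the add-one correction.
    """
    per_cage_stats = []
    for counts, labels, n_counted in zip(
        counts_by_cage, labels_by_cage, n_counted_by_cage
    ):
        n, k = len(labels), int(np.sum(labels))
        stats = [
            sum(counts[i] for i in combo) / n_counted
            for combo in itertools.combinations(range(n), k)
        ]
        per_cage_stats.append(stats)
    all_stats = [np.mean(combo) for combo in itertools.product(*per_cage_stats)]
    all_stats = np.asarray(all_stats)
    observed = np.mean(
        [
            np.dot(c, l) / n
            for c, l, n in zip(counts_by_cage, labels_by_cage, n_counted_by_cage)
        ]
    )
    center = all_stats.mean()
    # tie tolerance mirrors the implementation's handling of float-equal distances
    return np.mean(np.abs(all_stats - center) >= abs(observed - center) - 1e-9)


class TestShuffleNullTest:
    def test_observed_at_null_center_gives_p_one(self, small_roster):
        # every animal contributes equally: statistic invariant under relabeling
        animals = ["h1", "w1", "h2", "w2"] * 3
        ev = events_frame(
            [("c1", 1, float(i), animals[i], 1, 0) for i in range(12)]
        )
        out = behavior.shuffle_null_test(ev, small_roster, K=12, B=200, seed=0)
        assert out.loc[0, "p"] == 1.0

    def test_monte_carlo_matches_exhaustive_enumeration(self, small_roster):
        # 2 hAdsl + 2 WT in one cage: 6 distinct label assignments
        visits = ["h1"] * 5 + ["h2"] * 2 + ["w1"] * 2 + ["w2"] * 1
        ev = events_frame(
            [("c1", 1, float(i), a, 1, 0) for i, a in enumerate(visits)]
        )
        out = behavior.shuffle_null_test(ev, small_roster, K=10, B=10_000, seed=3)
        counts = np.array([5, 2, 2, 1], dtype=float)  # h1, h2, w1, w2
        labels = np.array([True, True, False, False])
        p_exact = exhaustive_permutation_p([counts], [labels], [10])
        assert out.loc[0, "p"] == pytest.approx(p_exact, abs=0.02)

    def test_monte_carlo_matches_enumeration_two_cages(self):
        roster = roster_frame(
            [
                ("a1", HADSL, "F", "c1"),
                ("a2", WT, "F", "c1"),
                ("a3", WT, "F", "c1"),
                ("b1", HADSL, "F", "c2"),
                ("b2", HADSL, "F", "c2"),
                ("b3", WT, "F", "c2"),
            ]
        )
        rows = [("c1", 1, float(i), a, 1, 0) for i, a in enumerate(
            ["a1", "a1", "a2", "a1", "a3", "a2"])]
        rows += [("c2", 1, float(i), a, 1, 0) for i, a in enumerate(
            ["b1", "b3", "b2", "b1", "b1", "b2"])]
        ev = events_frame(rows)
        out = behavior.shuffle_null_test(ev, roster, K=6, B=10_000, seed=11)
        p_exact = exhaustive_permutation_p(
            [np.array([3.0, 2.0, 1.0]), np.array([3.0, 2.0, 1.0])],
            [np.array([True, False, False]), np.array([True, True, False])],
            [6, 6],
        )
        assert out.loc[0, "p"] == pytest.approx(p_exact, abs=0.02)

    def test_p_at_least_one_over_b_plus_one(self, small_roster):
        ev = events_frame([("c1", 1, float(i), "h1", 1, 0) for i in range(10)])
        out = behavior.shuffle_null_test(ev, small_roster, K=10, B=200, seed=0)
        assert out.loc[0, "p"] >= 1 / 201
        assert out.loc[0, "p_adj"] == min(1.0, out.loc[0, "m"] * out.loc[0, "p"])

    def test_two_tailed_symmetry_under_label_swap(self, small_roster):
        """Swapping hAdsl and WT labels leaves the p-value unchanged."""
        visits = ["h1"] * 6 + ["h2"] * 1 + ["w1"] * 2 + ["w2"] * 1
        ev = events_frame(
            [("c1", 1, float(i), a, 1, 0) for i, a in enumerate(visits)]
        )
        swapped = small_roster.copy()
        swapped["genotype"] = swapped["genotype"].map({HADSL: WT, WT: HADSL})
        p1 = behavior.shuffle_null_test(ev, small_roster, K=10, B=5000, seed=5)
        p2 = behavior.shuffle_null_test(ev, swapped, K=10, B=5000, seed=5)
        assert p1.loc[0, "p"] == pytest.approx(p2.loc[0, "p"], abs=0.02)

    def test_bonferroni_family_override(self, small_roster, alternating_events):
        out = behavior.shuffle_null_test(
            alternating_events, small_roster, K=10, B=200, seed=0, family_m=20
        )
        assert out.loc[0, "m"] == 20
        assert out.loc[0, "p_adj"] == min(1.0, 20 * out.loc[0, "p"])


class TestVisitRatio:
    def test_equal_counts_give_one(self, small_roster, alternating_events):
        r = behavior.visit_ratio(alternating_events, small_roster, K=10)
        assert r.ratio == 1.0 and not r.infinite

    def test_four_to_one(self, small_roster):
        visits = ["h1", "h2", "h1", "w1", "h2"]
        ev = events_frame(
            [("c1", 1, float(i), a, 1, 0) for i, a in enumerate(visits)]
        )
        r = behavior.visit_ratio(ev, small_roster, K=5)
        assert r.ratio == 4.0 and r.n_hadsl == 4 and r.n_wt == 1

    def test_zero_wt_flagged_infinite(self, small_roster):
        ev = events_frame([("c1", 1, float(i), "h1", 1, 0) for i in range(5)])
        r = behavior.visit_ratio(ev, small_roster, K=5)
        assert r.infinite and np.isinf(r.ratio)

    def test_per_day_mode_pools_within_day(self, small_roster):
        rows = [("c1", 1, float(i), a, 1, 0) for i, a in enumerate(["h1", "h2", "w1"])]
        rows += [("c1", 2, float(i), a, 1, 0) for i, a in enumerate(["w1", "w2", "h1"])]
        out = behavior.visit_ratio(events_frame(rows), small_roster, K=3, mode="per_day")
        assert list(out["ratio"]) == [2.0, 0.5]

    def test_ratio_proportion_relation_single_day(self, small_roster):
        """Pooled from one day, ratio = p/(1-p) for the pooled proportion p."""
        visits = ["h1", "h2", "h1", "w1", "w2"]
        ev = events_frame(
            [("c1", 1, float(i), a, 1, 0) for i, a in enumerate(visits)]
        )
        r = behavior.visit_ratio(ev, small_roster, K=5)
        p = behavior.first_n_proportion(ev, small_roster, K=5).loc[0, "proportion_hadsl"]
        assert r.ratio == pytest.approx(p / (1 - p))


class TestFirstVisitorFraction:
    def test_direct_counts(self, small_roster):
        rows = []
        for day in range(1, 10):
            first = "h1" if day in (1, 3, 5) else "w1"
            rows.append(("c1", day, 1.0, first, 1, 0))
            rows.append(("c1", day, 2.0, "h2", 1, 0))
        out = behavior.first_visitor_fraction(events_frame(rows), small_roster)
        assert out.loc[0, "n_days"] == 9
        assert out.loc[0, "fraction_hadsl"] == pytest.approx(3 / 9)

    def test_all_days_hadsl(self, small_roster):
        rows = [("c1", d, 0.0, "h1", 1, 0) for d in range(1, 10)]
        out = behavior.first_visitor_fraction(events_frame(rows), small_roster)
        assert out.loc[0, "fraction_hadsl"] == 1.0

    def test_days_without_eligible_visits_excluded(self, small_roster):
        rows = [("c1", 1, 5.0, "h1", 1, 0), ("c1", 2, 1.0, "w1", 1, 0)]
        out = behavior.first_visitor_fraction(
            events_frame(rows), small_roster, onset=3.0
        )
        assert out.loc[0, "n_days"] == 1
        assert out.loc[0, "n_excluded_days"] == 1

    def test_onset_tie_break_is_deterministic(self, small_roster):
        # simultaneous first visits: animal id lexicographic order wins
        rows = [("c1", 1, 10.0, "w1", 1, 0), ("c1", 1, 10.0, "h1", 1, 0)]
        out = behavior.first_visitor_fraction(events_frame(rows), small_roster)
        assert out.loc[0, "fraction_hadsl"] == 1.0  # "h1" < "w1"


class TestCornerVisitBalance:
    def test_identical_counts_give_p_one(self, small_roster):
        rows = [
            ("c1", 1, float(i), a, 3, 0)
            for i, a in enumerate(["h1", "h2", "w1", "w2"] * 5)
        ]
        res = behavior.corner_visit_balance(
            events_frame(rows), small_roster, {2, 3, 4}, B=500, seed=0
        )
        assert res.p_two_tailed == 1.0
        assert res.observed_diff == 0.0

    def test_planted_tenfold_imbalance_detected(self):
        roster = roster_frame(
            [(f"h{i}", HADSL, "F", "c1") for i in range(5)]
            + [(f"w{i}", WT, "F", "c1") for i in range(5)]
        )
        rows = []
        t = 0.0
        for i in range(5):
            for _ in range(50):
                rows.append(("c1", 1, (t := t + 1.0), f"h{i}", 2, 0))
            for _ in range(5):
                rows.append(("c1", 1, (t := t + 1.0), f"w{i}", 2, 0))
        res = behavior.corner_visit_balance(
            events_frame(rows), roster, {2}, B=1000, seed=0
        )
        assert res.p_two_tailed < 0.01

    def test_empty_corner_set_rejected(self, small_roster, alternating_events):
        with pytest.raises(ValueError):
            behavior.corner_visit_balance(alternating_events, small_roster, set())


class TestTubeTest:
    @pytest.mark.parametrize(
        "wins,n,frac,p",
        [
            (3, 6, 0.5, 1.0),
            (6, 6, 1.0, 0.03125),  # 2 * 0.5**6
            (0, 6, 0.0, 0.03125),
        ],
    )
    def test_exact_binomial(self, wins, n, frac, p):
        winners = [HADSL] * wins + [WT] * (n - wins)
        res = behavior.tube_test_summary(winners)
        assert res.fraction_hadsl == frac
        assert res.p_two_sided == pytest.approx(p, abs=1e-12)

    def test_zero_matches_is_error(self):
        with pytest.raises(ValueError):
            behavior.tube_test_summary([])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="het"):
            behavior.tube_test_summary(["het"])
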