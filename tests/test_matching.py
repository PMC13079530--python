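"""Matching: distances, three methods, brute-force oracle, balance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from toxmatch.matching import (
    MatchSpec,
    balance_report,
    distance_matrix,
    exact_match,
    match_distance,
    nearest_neighbor_match,
    optimal_match,
    total_cost,
    _scales,
)

from conftest import make_participants


def cohort(rows):
    """rows: (id, case, age, sex, race, year[, alcohol, tobacco, adi])."""
    out = []
    for r in rows:
        pid, case, age, sex, race, year = r[:6]
        alcohol, tobacco, adi = (r[6:] + ("never", "never", 100.0))[:3] if len(r) > 6 else ("never", "never", 100.0)
        out.append((pid, -77.4, 37.5, year, "lung" if case else "none", case,
                    age, sex, race, "not_hispanic", alcohol, tobacco, adi))
    return make_participants(out)


class TestMatchDistance:
    def test_identical_covariates_zero(self):
        df = cohort([("a", 1, 50, "female", "white", 2015),
                     ("b", 0, 50, "female", "white", 2015)])
        spec = MatchSpec("nearest_neighbor")
        scales = _scales(df, spec.variables)
        assert match_distance(df.iloc[0], df.iloc[1], spec, scales) == 0.0

    def test_single_categorical_penalty(self):
        df = cohort([("a", 1, 50, "female", "white", 2015),
                     ("b", 0, 50, "male", "white", 2015)])
        spec = MatchSpec("nearest_neighbor")
        assert match_distance(df.iloc[0], df.iloc[1], spec, _scales(df, spec.variables)) == 1000.0

    def test_one_sd_age_difference_is_one(self):
        # ages {40, 60}: pre-match sample SD is sqrt(200); use it as the gap
        df = cohort([("a", 1, 40.0, "female", "white", 2015),
                     ("b", 0, 60.0, "female", "white", 2015)])
        spec = MatchSpec("nearest_neighbor")
        scales = _scales(df, spec.variables)
        df.loc[1, "age"] = 40.0 + scales["age"]
        assert match_distance(df.iloc[0], df.iloc[1], spec, scales) == pytest.approx(1.0)

    def test_exact_method_has_no_distance(self):
        df = cohort([("a", 1, 50, "female", "white", 2015)])
        with pytest.raises(ValueError):
            match_distance(df.iloc[0], df.iloc[0], MatchSpec("exact"))


class TestNearestNeighbor:
    def test_tie_break_lowest_control_ids(self):
        df = cohort([("case1", 1, 50, "female", "white", 2015)] +
                    [(f"ctl{i}", 0, 50, "female", "white", 2015) for i in (3, 1, 2)])
        sets = nearest_neighbor_match(df, MatchSpec("nearest_neighbor", ratio=2))
        assert sets[0].control_ids == ["ctl1", "ctl2"]

    def test_greedy_order_descending_age(self):
        # older case is served first and takes the shared best control
        df = cohort([
            ("old", 1, 70, "female", "white", 2015),
            ("young", 1, 40, "female", "white", 2015),
            ("c70", 0, 69, "female", "white", 2015),
            ("c41", 0, 41, "female", "white", 2015),
            ("c45", 0, 45, "female", "white", 2015),
        ])
        sets = nearest_neighbor_match(df, MatchSpec("nearest_neighbor", ratio=1))
        by_case = {s.case_id: s.control_ids for s in sets}
        assert by_case["old"] == ["c70"]
        assert by_case["young"] == ["c41"]

    def test_perfect_copies_match_at_zero(self):
        df = cohort([(f"case{i}", 1, 40 + i, "female", "white", 2015) for i in range(3)] +
                    [(f"ctl{i}", 0, 40 + i, "female", "white", 2015) for i in range(3)])
        spec = MatchSpec("nearest_neighbor", ratio=1)
        sets = nearest_neighbor_match(df, spec)
        assert len(sets) == 3
        assert total_cost(sets, df, spec) == 0.0

    def test_caliper_drops_cases(self):
        df = cohort([("case1", 1, 90, "female", "white", 2015),
                     ("ctl1", 0, 20, "female", "white", 2015)])
        with pytest.warns(UserWarning, match="no admissible"):
            sets = nearest_neighbor_match(df, MatchSpec("nearest_neighbor", ratio=1, caliper=0.5))
        assert sets == []


class TestExactMatch:
    def test_single_pair(self):
        df = cohort([("case1", 1, 52, "female", "white", 2015),
                     ("ctl1", 0, 53, "female", "white", 2015)])
        sets = exact_match(df, MatchSpec("exact", ratio=1))
        assert len(sets) == 1 and sets[0].control_ids == ["ctl1"]

    def test_case_without_stratum_controls_dropped(self):
        df = cohort([("case1", 1, 52, "female", "white", 2015),
                     ("case2", 1, 52, "male", "white", 2015),
                     ("ctl1", 0, 53, "female", "white", 2015)])
        with pytest.warns(UserWarning, match="dropped 1 case"):
            sets = exact_match(df, MatchSpec("exact", ratio=1))
        assert [s.case_id for s in sets] == ["case1"]

    def test_partition_two_cases_three_controls(self):
        df = cohort([("caseA", 1, 51, "female", "white", 2015),
                     ("caseB", 1, 52, "female", "white", 2015)] +
                    [(f"ctl{i}", 0, 50 + i, "female", "white", 2015) for i in range(3)])
        sets = exact_match(df, MatchSpec("exact", ratio=2, seed=4))
        sizes = sorted(len(s.control_ids) for s in sets)
        assert sizes == [1, 2]
        union = sorted(c for s in sets for c in s.control_ids)
        assert union == ["ctl0", "ctl1", "ctl2"]

    def test_age_bins_respected(self):
        # ages 52 and 58 fall in different 5-year bins -> no match
        from toxmatch.matching import MatchingError
        df = cohort([("case1", 1, 52, "female", "white", 2015),
                     ("ctl1", 0, 58, "female", "white", 2015)])
        with pytest.raises(MatchingError), pytest.warns(UserWarning):
            exact_match(df, MatchSpec("exact", ratio=1))


def brute_force_min_cost(cost):
    n, m = cost.shape
    best = np.inf
    for perm in itertools.permutations(range(m), n):
        best = min(best, sum(cost[i, j] for i, j in enumerate(perm)))
    return best


def random_instance(rng, n_cases, n_controls):
    rows = []
    for i in range(n_cases):
        rows.append((f"case{i}", 1, float(rng.uniform(30, 80)),
                     rng.choice(["female", "male"]), "white", int(rng.integers(2014, 2017)),
                     rng.choice(["never", "current"]), "never", float(rng.normal(100, 20))))
    for j in range(n_controls):
        rows.append((f"ctl{j}", 0, float(rng.uniform(30, 80)),
                     rng.choice(["female", "male"]), "white", int(rng.integers(2014, 2017)),
                     rng.choice(["never", "current"]), "never", float(rng.normal(100, 20))))
    return cohort(rows)


class TestOptimalMatch:
    def test_two_by_two_diagonal(self):
        df = cohort([("case0", 1, 40, "female", "white", 2015),
                     ("case1", 1, 60, "female", "white", 2015),
                     ("ctl0", 0, 41, "female", "white", 2015),
                     ("ctl1", 0, 59, "female", "white", 2015)])
        sets = optimal_match(df, MatchSpec("optimal", ratio=1))
        by_case = {s.case_id: s.control_ids for s in sets}
        assert by_case == {"case0": ["ctl0"], "case1": ["ctl1"]}

    def test_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(21)
        spec = MatchSpec("optimal", ratio=1)
        for _ in range(50):
            df = random_instance(rng, int(rng.integers(2, 7)), int(rng.integers(2, 7)))
            n_cases = int((df["case"] == 1).sum())
            if n_cases > int((df["case"] == 0).sum()):
                continue
            cases = df[df["case"] == 1].reset_index(drop=True)
            controls = df[df["case"] == 0].reset_index(drop=True)
            cost = distance_matrix(cases, controls, spec, _scales(df, spec.variables))
            sets = optimal_match(df, spec)
            assert total_cost(sets, df, spec) == pytest.approx(brute_force_min_cost(cost), rel=1e-9)

    def test_optimal_never_worse_than_greedy(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            df = random_instance(rng, 5, 15)
            opt = total_cost(optimal_match(df, MatchSpec("optimal", ratio=2)), df,
                             MatchSpec("optimal", ratio=2))
            greedy_sets = nearest_neighbor_match(df, MatchSpec("optimal", ratio=2))
            grd = total_cost(greedy_sets, df, MatchSpec("optimal", ratio=2))
            assert opt <= grd + 1e-9

    def test_without_replacement_and_determinism(self):
        rng = np.random.default_rng(23)
        df = random_instance(rng, 6, 20)
        spec = MatchSpec("optimal", ratio=3)
        s1, s2 = optimal_match(df, spec), optimal_match(df, spec)
        ids1 = [c for s in s1 for c in s.control_ids]
        assert len(ids1) == len(set(ids1))
        assert [(s.case_id, s.control_ids) for s in s1] == \
            [(s.case_id, s.control_ids) for s in s2]

    def test_control_deficit_warns_partial(self):
        df = random_instance(np.random.default_rng(24), 4, 6)
        with pytest.warns(UserWarning, match="fewer controls"):
            sets = optimal_match(df, MatchSpec("optimal", ratio=2))
        assert sum(len(s.control_ids) for s in sets) == 6


class TestBalanceReport:
    def test_copied_controls_zero_post_smd(self):
        df = cohort([(f"case{i}", 1, 40.0 + i, "female", "white", 2015) for i in range(4)] +
                    [(f"ctl{i}", 0, 40.0 + i, "female", "white", 2015) for i in range(4)] +
                    [(f"far{i}", 0, 80.0, "female", "white", 2015) for i in range(4)])
        spec = MatchSpec("nearest_neighbor", ratio=1)
        sets = nearest_neighbor_match(df, spec)
        rep = balance_report(sets, df, spec)
        age = rep[(rep["variable"] == "age")]
        assert age["post"].abs().iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert abs(age["pre"].iloc[0]) > 0

    def test_matching_reduces_age_imbalance(self, small_cohort):
        _, _, participants, _ = small_cohort
        spec = MatchSpec("nearest_neighbor", ratio=2)
        sets = nearest_neighbor_match(participants, spec)
        rep = balance_report(sets, participants, spec)
        age = rep[rep["variable"] == "age"].iloc[0]
        assert abs(age["post"]) <= abs(age["pre"])
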