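"""Exposure assessment: geometry, lag windows, grid, dichotomization, filter."""

import numpy as np
import pandas as pd
import pytest

from toxmatch import exposure as expo
from toxmatch.exposure import (
    BUFFERS_KM,
    EARTH_RADIUS_KM,
    ExposureDefinition,
    ExposureMatrix,
    compute_exposure,
    compute_exposure_matrix,
    dichotomize,
    enumerate_grid,
    haversine_km,
    lag_window,
    prevalence_filter,
)

from conftest import km_to_deg_lat, make_facilities, make_participants, random_toy_tables


class TestHaversine:
    def test_identity(self):
        assert haversine_km(-77.4, 37.5, -77.4, 37.5) == 0.0

    def test_antipodal_half_circumference(self):
        assert haversine_km(0.0, 0.0, 180.0, 0.0) == pytest.approx(np.pi * EARTH_RADIUS_KM)

    def test_against_sklearn_great_circle(self):
        # independent spherical implementation (sklearn works in radians on the
        # unit sphere; scale by the same radius)
        from sklearn.metrics.pairwise import haversine_distances

        rng = np.random.default_rng(7)
        lon1, lon2 = rng.uniform(-180, 180, (2, 40))
        lat1, lat2 = rng.uniform(-90, 90, (2, 40))
        ours = haversine_km(lon1, lat1, lon2, lat2)
        a = np.radians(np.column_stack([lat1, lon1]))
        b = np.radians(np.column_stack([lat2, lon2]))
        theirs = np.array([haversine_distances(a[i:i + 1], b[i:i + 1])[0, 0]
                           for i in range(40)]) * EARTH_RADIUS_KM
        np.testing.assert_allclose(ours, theirs, rtol=1e-12)

    def test_richmond_one_degree_lon(self):
        from sklearn.metrics.pairwise import haversine_distances

        ours = haversine_km(-77.4360, 37.5407, -76.4360, 37.5407)
        oracle = haversine_distances(
            np.radians([[37.5407, -77.4360]]), np.radians([[37.5407, -76.4360]])
        )[0, 0] * EARTH_RADIUS_KM
        assert ours == pytest.approx(oracle, rel=1e-12)

    @pytest.mark.parametrize("bad", [(np.nan, 0, 0, 0), (0, 95.0, 0, 0), (200.0, 0, 0, 0)])
    def test_invalid_coordinates(self, bad):
        with pytest.raises(ValueError):
            haversine_km(*bad)


class TestLagWindow:
    @pytest.mark.parametrize("visit, lag, expected", [
        (2015, 1, [2014]),
        (2015, 5, [2010, 2011, 2012, 2013, 2014]),
        (2010, 3, [2007, 2008, 2009]),
    ])
    def test_windows_exclude_visit_year(self, visit, lag, expected):
        assert list(lag_window(visit, lag)) == expected

    @pytest.mark.parametrize("lag", [0, 6, -1])
    def test_lag_out_of_range(self, lag):
        with pytest.raises(expo.ConfigurationError):
            lag_window(2015, lag)


class TestGrid:
    def test_sixty_definitions_per_agent(self):
        assert len(enumerate_grid(["chromium"])) == 60

    def test_full_default_grid(self):
        grid = enumerate_grid(expo.DEFAULT_AGENTS)
        assert len(grid) == 660
        assert len({d.id for d in grid}) == 660
        assert grid == sorted(grid)  # deterministic lexical order

    def test_empty_and_duplicate_agents(self):
        with pytest.raises(expo.ConfigurationError):
            enumerate_grid([])
        with pytest.raises(expo.ConfigurationError):
            enumerate_grid(["chromium", "chromium"])

    def test_id_round_trip(self):
        d = ExposureDefinition("benzene", "idw_hazard", 5.0, 3)
        assert ExposureDefinition.from_id(d.id) == d


def brute_force_exposure(participant, defn, facilities):
    """Independent double loop over facility-year records."""
    present, ids, idw = 0, set(), 0.0
    lo, hi = participant["visit_year"] - defn.lag_years, participant["visit_year"] - 1
    for _, f in facilities.iterrows():
        if f["agent"] != defn.agent or not (lo <= f["year"] <= hi):
            continue
        d = haversine_km(participant["lon"], participant["lat"], f["lon"], f["lat"])
        if d > defn.buffer_km:
            continue
        present = 1
        ids.add(f["facility_id"])
        idw += f["modeled_hazard"] / max(d, expo.IDW_DISTANCE_FLOOR_KM)
    return {"presence": float(present), "count": float(len(ids)), "idw_hazard": idw}[defn.metric]


class TestComputeExposure:
    def test_empty_buffer_yields_zero(self):
        fac = make_facilities([("F0", -70.0, 30.0, "chromium", 2014, 5.0)])
        p = pd.Series({"lon": -77.4, "lat": 37.5, "visit_year": 2015})
        for metric in expo.METRICS:
            assert compute_exposure(p, ExposureDefinition("chromium", metric, 5.0, 5), fac) == 0.0

    def test_single_facility_two_window_years(self):
        # facility exactly 4 km due north, hazard 8.0 reported in 2 window years
        lat0 = 37.0
        fac = make_facilities([
            ("F0", -77.4, lat0 + km_to_deg_lat(4.0), "chromium", 2013, 8.0),
            ("F0", -77.4, lat0 + km_to_deg_lat(4.0), "chromium", 2014, 8.0),
        ])
        p = pd.Series({"lon": -77.4, "lat": lat0, "visit_year": 2015})
        d5 = ExposureDefinition("chromium", "presence", 5.0, 5)
        assert compute_exposure(p, d5, fac) == 1.0
        assert compute_exposure(p, ExposureDefinition("chromium", "count", 5.0, 5), fac) == 1.0
        idw = compute_exposure(p, ExposureDefinition("chromium", "idw_hazard", 5.0, 5), fac)
        assert idw == pytest.approx(2 * 8.0 / 4.0, rel=1e-9)

    def test_out_of_buffer_facility_excluded_from_count(self):
        lat0 = 37.0
        fac = make_facilities([
            ("F0", -77.4, lat0 + km_to_deg_lat(3.0), "chromium", 2014, 1.0),
            ("F1", -77.4, lat0 + km_to_deg_lat(12.0), "chromium", 2014, 1.0),
        ])
        p = pd.Series({"lon": -77.4, "lat": lat0, "visit_year": 2015})
        assert compute_exposure(p, ExposureDefinition("chromium", "count", 10.0, 5), fac) == 1.0

    def test_matrix_equals_bruteforce_on_random_toys(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            fac, part = random_toy_tables(rng, n_participants=12)
            grid = enumerate_grid(["chromium", "benzene"],
                                  buffers_km=(5.0, 20.0), lags_years=(1, 5))
            mat = compute_exposure_matrix(part, fac, grid)
            for d in grid:
                for _, p in part.iterrows():
                    expected = brute_force_exposure(p, d, fac)
                    got = mat.raw.loc[p["participant_id"], d.id]
                    if d.metric == "idw_hazard":
                        # summation order differs between the vectorized path
                        # and the loop oracle; equality is to float rounding
                        assert got == pytest.approx(expected, rel=1e-12)
                    else:
                        assert got == expected

    def test_buffer_and_lag_monotonicity_and_additivity(self):
        rng = np.random.default_rng(5)
        fac, part = random_toy_tables(rng, n_facilities=15, n_participants=20)
        grid = enumerate_grid(["chromium"])
        mat = compute_exposure_matrix(part, fac, grid).raw
        for metric in expo.METRICS:
            for lag in (1, 3, 5):
                cols = [f"chromium|{metric}|{int(b)}|{lag}" for b in BUFFERS_KM]
                vals = mat[cols].to_numpy()
                assert np.all(np.diff(vals, axis=1) >= 0), "buffer monotonicity"
            for b in (2, 10):
                cols = [f"chromium|{metric}|{b}|{lag}" for lag in range(1, 6)]
                vals = mat[cols].to_numpy()
                assert np.all(np.diff(vals, axis=1) >= 0), "lag monotonicity"
        # additivity of idw over disjoint single-year windows: shift visit years
        lag5 = mat["chromium|idw_hazard|20|5"].to_numpy()
        single = np.zeros_like(lag5)
        for shift in range(5):
            shifted = part.copy()
            shifted["visit_year"] = part["visit_year"] - shift
            m1 = compute_exposure_matrix(shifted, fac, [ExposureDefinition("chromium", "idw_hazard", 20.0, 1)])
            single += m1.raw["chromium|idw_hazard|20|1"].to_numpy()
        np.testing.assert_allclose(single, lag5, rtol=1e-12)


def _matrix_from_values(values: dict, case):
    raw = pd.DataFrame(values, index=[f"P{i}" for i in range(len(case))])
    return ExposureMatrix(raw=raw, case=pd.Series(case, index=raw.index))


class TestDichotomize:
    def test_presence_unchanged(self):
        m = _matrix_from_values({"a|presence|5|1": [0, 1, 1]}, [1, 0, 0])
        dichotomize(m)
        assert m.coding["a|presence|5|1"].tolist() == [0, 1, 1]
        assert m.status["a|presence|5|1"] == "ok"

    def test_idw_strict_median_of_positives(self):
        m = _matrix_from_values({"a|idw_hazard|5|1": [0, 0, 2, 4, 6]}, [1, 0, 0, 0, 0])
        dichotomize(m)
        assert m.coding["a|idw_hazard|5|1"].tolist() == [0, 0, 0, 0, 1]
        assert m.idw_cuts["a|idw_hazard|5|1"] == 4.0

    def test_count_redundant_when_max_one(self):
        m = _matrix_from_values({"a|count|5|1": [0, 1, 1, 0]}, [1, 0, 0, 0])
        dichotomize(m)
        assert m.status["a|count|5|1"] == "redundant"

    def test_count_codes_at_two_or_more(self):
        m = _matrix_from_values({"a|count|5|1": [0, 1, 2, 3]}, [1, 0, 0, 0])
        dichotomize(m)
        assert m.coding["a|count|5|1"].tolist() == [0, 0, 1, 1]
        assert m.status["a|count|5|1"] == "ok"

    def test_all_zero_column_non_informative(self):
        m = _matrix_from_values({"a|presence|5|1": [0, 0, 0]}, [1, 0, 0])
        dichotomize(m)
        assert m.status["a|presence|5|1"] == "non_informative"
        assert prevalence_filter(m) == []


class TestPrevalenceFilter:
    def _matrix(self, n_exp_cases, n_exp_controls, n_cases=40, n_controls=600):
        coding = [1] * n_exp_cases + [0] * (n_cases - n_exp_cases) + \
                 [1] * n_exp_controls + [0] * (n_controls - n_exp_controls)
        case = [1] * n_cases + [0] * n_controls
        m = _matrix_from_values({"a|presence|5|1": coding}, case)
        return dichotomize(m)

    def test_boundary_exactly_ten_retained(self):
        m = self._matrix(10, 10)
        assert [d.id for d in prevalence_filter(m)] == ["a|presence|5|1"]

    def test_nine_exposed_cases_dropped(self):
        assert prevalence_filter(self._matrix(9, 500)) == []

    def test_participant_order_invariance(self):
        rng = np.random.default_rng(3)
        m = self._matrix(15, 30)
        perm = rng.permutation(len(m.raw))
        shuffled = ExposureMatrix(raw=m.raw.iloc[perm], case=m.case.iloc[perm])
        dichotomize(shuffled)
        assert [d.id for d in prevalence_filter(shuffled)] == \
            [d.id for d in prevalence_filter(m)]
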