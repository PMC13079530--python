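"""Geospatial exposure assessment around industrial point sources.

Exposure to an emitted agent is summarised per participant through a grid of
definitions: metric (facility presence, distinct-facility count, or
inverse-distance-weighted modeled hazard) x circular buffer radius x
cumulative reporting lag. Facilities contribute when they report the agent
in a calendar year inside the lag window and lie within the buffer around
the participant's residence. Raw metrics are dichotomized into binary
analysis codings and a minimum-prevalence filter (at least 10 exposed cases
and 10 exposed controls) selects the definitions carried into modelling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088
IDW_DISTANCE_FLOOR_KM = 0.1
PREVALENCE_MIN_EXPOSED = 10

METRICS = ("presence", "count", "idw_hazard")
BUFFERS_KM = (2.0, 5.0, 10.0, 20.0)
LAGS_YEARS = (1, 2, 3, 4, 5)

#: the eleven carcinogenic TRI agents analysed by default
DEFAULT_AGENTS = (
    "antimony",
    "arsenic",
    "benzene",
    "beryllium",
    "cadmium",
    "chromium",
    "cobalt",
    "ethylene_oxide",
    "formaldehyde",
    "hydrazine",
    "nickel",
)

FACILITY_COLUMNS = ["facility_id", "lon", "lat", "agent", "year", "modeled_hazard"]
PARTICIPANT_COLUMNS = [
    "participant_id", "lon", "lat", "visit_year", "cancer_type", "case",
    "age", "sex", "race", "ethnicity", "alcohol", "tobacco", "adi_std",
]


class ConfigurationError(ValueError):
    """Raised for invalid grid or window configuration."""


@dataclass(frozen=True, order=True)
class ExposureDefinition:
    """One cell of the exposure design grid: (agent, metric, buffer, lag)."""

    agent: str
    metric: str
    buffer_km: float
    lag_years: int

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ConfigurationError(f"unknown metric {self.metric!r}")
        if self.lag_years < 1 or self.lag_years > 5:
            raise ConfigurationError("lag_years must be in 1..5")
        if self.buffer_km <= 0:
            raise ConfigurationError("buffer_km must be positive")

    @property
    def id(self) -> str:
        buf = int(self.buffer_km) if float(self.buffer_km).is_integer() else self.buffer_km
        return f"{self.agent}|{self.metric}|{buf}|{self.lag_years}"

    @classmethod
    def from_id(cls, definition_id: str) -> "ExposureDefinition":
        agent, metric, buf, lag = definition_id.split("|")
        return cls(agent=agent, metric=metric, buffer_km=float(buf), lag_years=int(lag))


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in km on a sphere of radius 6371.0088 km.

    Accepts scalars or broadcastable arrays of WGS84 decimal degrees.
    """
    lon1, lat1, lon2, lat2 = (np.asarray(v, dtype=float) for v in (lon1, lat1, lon2, lat2))
    if not all(np.all(np.isfinite(v)) for v in (lon1, lat1, lon2, lat2)):
        raise ValueError("non-finite coordinates")
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any(np.abs(lon1) > 180) or np.any(np.abs(lon2) > 180):
        raise ValueError("longitude out of range [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    return float(d) if d.ndim == 0 else d


def lag_window(visit_year: int, lag_years: int) -> range:
    """Inclusive calendar-year window [visit_year - lag, visit_year - 1].

    The visit year itself is excluded: reporting data are used from years
    strictly prior to the visit date, up to five years back.
    """
    if lag_years < 1 or lag_years > 5:
        raise ConfigurationError("lag_years must be in 1..5")
    return range(visit_year - lag_years, visit_year)


def enumerate_grid(
    agents,
    metrics=METRICS,
    buffers_km=BUFFERS_KM,
    lags_years=LAGS_YEARS,
) -> list[ExposureDefinition]:
    """Cross-product grid of definitions, 3 x 4 x 5 = 60 per agent by default.

    Deterministic (agent, metric, buffer, lag) lexical order.
    """
    agents = list(agents)
    if not agents:
        raise ConfigurationError("agent list is empty")
    if len(set(agents)) != len(agents):
        raise ConfigurationError("duplicate agent names")
    return [
        ExposureDefinition(a, m, float(b), int(l))
        for a, m, b, l in itertools.product(
            agents, sorted(metrics), sorted(float(b) for b in buffers_km),
            sorted(int(l) for l in lags_years),
        )
    ]


def compute_exposure(
    participant: pd.Series,
    defn: ExposureDefinition,
    facilities: pd.DataFrame,
    idw_power: float = 1.0,
) -> float:
    """Raw exposure value for a single participant and definition.

    Scalar reference path; `compute_exposure_matrix` is the vectorized
    equivalent used by the pipeline (tested to agree exactly).
    """
    window = lag_window(int(participant["visit_year"]), defn.lag_years)
    fac = facilities[
        (facilities["agent"] == defn.agent)
        & facilities["year"].isin(list(window))
    ]
    if fac.empty:
        return 0.0
    d = haversine_km(participant["lon"], participant["lat"],
                     fac["lon"].to_numpy(), fac["lat"].to_numpy())
    inside = d <= defn.buffer_km
    fac = fac[inside]
    if fac.empty:
        return 0.0
    if defn.metric == "presence":
        return 1.0
    if defn.metric == "count":
        return float(fac["facility_id"].nunique())
    w = 1.0 / np.maximum(np.asarray(d)[inside], IDW_DISTANCE_FLOOR_KM) ** idw_power
    return float(np.sum(fac["modeled_hazard"].to_numpy() * w))


@dataclass
class ExposureMatrix:
    """Raw exposure values plus binary analysis codings for a cohort.

    raw     : participants x definitions (float values of the raw metric)
    coding  : binary analysis codings, populated by :func:`dichotomize`
    status  : per-column flag ('raw', then 'ok' / 'redundant' / 'non_informative')
    case    : per-participant case indicator aligned to ``raw.index``
    """

    raw: pd.DataFrame
    case: pd.Series
    coding: pd.DataFrame | None = None
    status: pd.Series | None = None
    idw_cuts: dict[str, float] = field(default_factory=dict)

    @property
    def definitions(self) -> list[ExposureDefinition]:
        return [ExposureDefinition.from_id(c) for c in self.raw.columns]

    def exposed_counts(self) -> pd.DataFrame:
        """Exposed-case / exposed-control counts per binary-coded column."""
        if self.coding is None:
            raise ValueError("call dichotomize() first")
        is_case = self.case.to_numpy().astype(bool)
        coded = self.coding.to_numpy().astype(bool)
        return pd.DataFrame(
            {
                "exposed_cases": coded[is_case].sum(axis=0),
                "exposed_controls": coded[~is_case].sum(axis=0),
            },
            index=self.coding.columns,
        )


def compute_exposure_matrix(
    participants: pd.DataFrame,
    facilities: pd.DataFrame,
    definitions: list[ExposureDefinition],
    idw_power: float = 1.0,
) -> ExposureMatrix:
    """Vectorized raw-exposure computation for every (participant, definition).

    Per agent, facility-year reports are pivoted to a facility x year table of
    any-report flags and hazard sums; cumulative lag windows then reduce to
    prefix-sum differences, and buffers to a single participant-facility
    great-circle distance matrix.
    """
    part = participants.reset_index(drop=True)
    n = len(part)
    values = {d.id: np.zeros(n) for d in definitions}
    by_agent: dict[str, list[ExposureDefinition]] = {}
    for d in definitions:
        by_agent.setdefault(d.agent, []).append(d)

    p_lon = part["lon"].to_numpy(float)
    p_lat = part["lat"].to_numpy(float)
    p_year = part["visit_year"].to_numpy(int)

    for agent, defs in by_agent.items():
        fac = facilities[facilities["agent"] == agent]
        if fac.empty:
            continue
        # unique facilities (one location each) and a facility x year layout
        fpos = fac.groupby("facility_id")[["lon", "lat"]].first()
        fids = fpos.index.to_numpy()
        y_min, y_max = int(fac["year"].min()), int(fac["year"].max())
        n_years = y_max - y_min + 1
        fidx = {f: i for i, f in enumerate(fids)}
        any_rep = np.zeros((len(fids), n_years))
        haz = np.zeros((len(fids), n_years))
        rows = fac["facility_id"].map(fidx).to_numpy()
        cols = fac["year"].to_numpy(int) - y_min
        any_rep[rows, cols] = 1.0
        haz[rows, cols] = fac["modeled_hazard"].to_numpy(float)
        # prefix sums over years: window [a, b] -> cum[:, b+1] - cum[:, a]
        cum_any = np.concatenate([np.zeros((len(fids), 1)), np.cumsum(any_rep, axis=1)], axis=1)
        cum_haz = np.concatenate([np.zeros((len(fids), 1)), np.cumsum(haz, axis=1)], axis=1)

        dist = haversine_km(p_lon[:, None], p_lat[:, None],
                            fpos["lon"].to_numpy()[None, :], fpos["lat"].to_numpy()[None, :])
        dist = np.atleast_2d(dist)
        inv_w = 1.0 / np.maximum(dist, IDW_DISTANCE_FLOOR_KM) ** idw_power

        for vy in np.unique(p_year):
            sel = np.flatnonzero(p_year == vy)
            for lag in sorted({d.lag_years for d in defs}):
                a = max(int(vy) - lag, y_min)
                b = min(int(vy) - 1, y_max)
                if a > b:
                    continue
                w_any = (cum_any[:, b - y_min + 1] - cum_any[:, a - y_min]) > 0
                w_haz = cum_haz[:, b - y_min + 1] - cum_haz[:, a - y_min]
                for d in defs:
                    if d.lag_years != lag:
                        continue
                    inbuf = dist[sel] <= d.buffer_km
                    if d.metric == "presence":
                        v = (inbuf & w_any[None, :]).any(axis=1).astype(float)
                    elif d.metric == "count":
                        v = (inbuf & w_any[None, :]).sum(axis=1).astype(float)
                    else:
                        v = (inbuf * inv_w[sel]) @ w_haz
                    values[d.id][sel] = v

    raw = pd.DataFrame(values, index=part["participant_id"])
    case = pd.Series(part["case"].to_numpy(int), index=raw.index, name="case")
    return ExposureMatrix(raw=raw, case=case)


def dichotomize(matrix: ExposureMatrix) -> ExposureMatrix:
    """Attach binary analysis codings to every column of the matrix.

    presence: already binary, unchanged. count: 1 iff count >= 2, provided
    some participant has >= 2 in-buffer facilities; otherwise the column
    duplicates presence and is flagged 'redundant'. idw_hazard: 1 iff the
    value strictly exceeds the median of the positive values pooled over the
    whole cohort (cases + controls, pre-matching). All-zero columns are
    flagged 'non_informative'. Only 'ok' columns are candidates for testing.
    """
    coding = {}
    status = {}
    cuts = {}
    for col in matrix.raw.columns:
        defn = ExposureDefinition.from_id(col)
        x = matrix.raw[col].to_numpy(float)
        if not np.any(x > 0):
            coding[col] = np.zeros_like(x, dtype=int)
            status[col] = "non_informative"
            continue
        if defn.metric == "presence":
            coding[col] = (x > 0).astype(int)
            status[col] = "ok"
        elif defn.metric == "count":
            if np.max(x) >= 2:
                coding[col] = (x >= 2).astype(int)
                status[col] = "ok"
            else:
                coding[col] = (x > 0).astype(int)
                status[col] = "redundant"
        else:
            pos = x[x > 0]
            cut = float(np.median(pos))
            cuts[col] = cut
            coding[col] = (x > cut).astype(int)
            status[col] = "ok"
    matrix.coding = pd.DataFrame(coding, index=matrix.raw.index)
    matrix.status = pd.Series(status, name="status")
    matrix.idw_cuts = cuts
    return matrix


def prevalence_filter(
    matrix: ExposureMatrix, min_exposed: int = PREVALENCE_MIN_EXPOSED
) -> list[ExposureDefinition]:
    """Definitions retained for modelling: binary coding has at least
    ``min_exposed`` exposed cases AND exposed controls, and the column is
    not flagged redundant or non-informative."""
    if matrix.coding is None or matrix.status is None:
        raise ValueError("call dichotomize() first")
    counts = matrix.exposed_counts()
    keep = []
    for col in matrix.coding.columns:
        if matrix.status[col] != "ok":
            continue
        row = counts.loc[col]
        if row["exposed_cases"] >= min_exposed and row["exposed_controls"] >= min_exposed:
            keep.append(ExposureDefinition.from_id(col))
    return keep


def definitions_table(matrix: ExposureMatrix, retained: list[ExposureDefinition]) -> pd.DataFrame:
    """Per-definition audit table: status, exposed counts, retained flag."""
    counts = matrix.exposed_counts()
    kept = {d.id for d in retained}
    rows = []
    for col in matrix.coding.columns:
        d = ExposureDefinition.from_id(col)
        rows.append(
            {
                "definition_id": col,
                "agent": d.agent,
                "metric": d.metric,
                "buffer_km": d.buffer_km,
                "lag_years": d.lag_years,
                "status": matrix.status[col],
                "exposed_cases": int(counts.loc[col, "exposed_cases"]),
                "exposed_controls": int(counts.loc[col, "exposed_controls"]),
                "retained": col in kept,
            }
        )
    return pd.DataFrame(rows)
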