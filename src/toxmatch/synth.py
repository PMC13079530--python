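"""Synthetic facility-emissions and participant tables with known truth.

The generator emulates a TRI/RSEI-style extract (facility-year reports of a
toxicity-modeled hazard) and a matched case-control participant table, at a
reduced scale, with case status drawn from an explicit logistic model whose
exposure and confounder coefficients are configurable. Because the truth is
known, every downstream stage — exposure assessment, matching, conditional
logistic regression, consensus inference — can be validated for parameter
recovery and error control without access to any real cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import exposure as expo
from .exposure import DEFAULT_AGENTS, ExposureDefinition, enumerate_grid

# category frequencies loosely matching a mid-Atlantic primary-care control
# population (sex near parity; White/Black plurality; mostly non-Hispanic;
# large unknown strata for self-reported alcohol/tobacco)
DEFAULT_COVARIATE_FREQS = {
    "sex": {"female": 0.54, "male": 0.46},
    "race": {"white": 0.46, "black": 0.41, "asian": 0.03, "other": 0.10},
    "ethnicity": {"not_hispanic": 0.94, "hispanic": 0.04, "unknown": 0.02},
    "alcohol": {"current": 0.36, "past": 0.06, "never": 0.25, "unknown": 0.33},
    "tobacco": {"current": 0.18, "past": 0.14, "never": 0.42, "unknown": 0.26},
}


class SimulationError(RuntimeError):
    """Raised when target case/control counts cannot be accrued."""


class DegenerateScaleError(ValueError):
    """Raised when a scale statistic is zero (e.g. constant ADI input)."""


@dataclass
class SimConfig:
    """Configuration of the synthetic study.

    The spatial region is a lon/lat bounding box (decimal degrees, roughly
    central Virginia by default); facilities and residences are placed inside
    it. ``true_log_or`` maps exposure-definition ids (``agent|metric|buffer|lag``)
    or bare agent names (expanded to that agent's presence / 10 km / lag-5
    definition) to true log odds ratios applied on the binary codings.
    ``confounder_log_or`` keys are ``age`` (per +1 SD of 10 years around 50),
    ``adi_std`` (per +1 SD of the standardized index), or ``var=level``
    indicators such as ``tobacco=current``.
    """

    seed: int = 0
    region: tuple[float, float, float, float] = (-79.5, -76.5, 36.5, 38.5)  # lon_min, lon_max, lat_min, lat_max
    n_cases: int = 300
    n_controls: int = 1500
    years: tuple[int, int] = (2010, 2023)
    agents: tuple[str, ...] = DEFAULT_AGENTS
    facilities_per_agent: int = 15
    hazard_log_mean: float = 8.0
    hazard_log_sd: float = 2.0
    facility_persistence: float = 0.8
    facility_clusters: int = 0  # 0 = uniform placement; >0 = Gaussian blobs
    cluster_sd_deg: float = 0.15
    covariate_freqs: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_FREQS.items()})
    age_mean_case: float = 60.0
    age_mean_control: float = 42.0
    age_sd: float = 14.0
    adi_raw_mean: float = 50.0
    adi_raw_sd: float = 25.0
    true_log_or: dict = field(default_factory=dict)
    baseline_logit: float = -1.5
    confounder_log_or: dict = field(default_factory=dict)
    cancer_type: str = "breast"
    max_candidates: int = 2_000_000
    batch_size: int = 4000

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.n_controls < self.n_cases:
            raise ValueError("n_controls must be >= n_cases")
        lon0, lon1, lat0, lat1 = self.region
        if not (lon1 > lon0 and lat1 > lat0):
            raise ValueError("degenerate region bounding box")
        if not 0.0 <= self.facility_persistence <= 1.0:
            raise ValueError("facility_persistence must be in [0, 1]")
        if self.hazard_log_sd <= 0:
            raise ValueError("hazard_log_sd must be positive")
        if not self.agents:
            raise expo.ConfigurationError("agent list is empty")
        for var, freqs in self.covariate_freqs.items():
            tot = sum(freqs.values())
            if abs(tot - 1.0) > 1e-8:
                raise ValueError(f"category probabilities for {var} sum to {tot}, not 1")
            if any(p < 0 or p > 1 for p in freqs.values()):
                raise ValueError(f"category probabilities for {var} outside [0, 1]")

    def resolved_effects(self) -> dict[str, float]:
        """Expand agent-name keys of ``true_log_or`` to definition ids."""
        out: dict[str, float] = {}
        for key, lor in self.true_log_or.items():
            if "|" in key:
                out[ExposureDefinition.from_id(key).id] = float(lor)
            else:
                if key not in self.agents:
                    raise ValueError(f"effect on unknown agent {key!r}")
                out[ExposureDefinition(key, "presence", 10.0, 5).id] = float(lor)
        return out


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort.

    ``exposures`` holds the raw exposure value of every emitted participant
    for every definition of the full grid; regenerating them with the
    exposure module from the emitted tables must reproduce them exactly.
    """

    exposures: pd.DataFrame
    linear_predictor: pd.Series
    case: pd.Series
    effects: dict[str, float]
    config: SimConfig

    def to_json(self, path) -> None:
        payload = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
            "effects": self.effects,
            "n_cases": int(self.case.sum()),
            "n_controls": int((1 - self.case).sum()),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def standardize_adi(raw_values) -> np.ndarray:
    """Standardize a raw deprivation index to mean 100, sample SD 20.

    Uses the sample (n-1) standard deviation: out = 100 + 20*(x - mean)/sd.
    """
    x = np.asarray(raw_values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateScaleError("constant input: standardized scale undefined")
    return 100.0 + 20.0 * (x - x.mean()) / sd


def generate_facilities(config: SimConfig) -> pd.DataFrame:
    """Facility-year emission reports.

    Each agent gets ``facilities_per_agent`` facilities placed uniformly in
    the region (or around Gaussian cluster centres when
    ``facility_clusters`` > 0, mimicking industrial corridors). For every
    calendar year from 5 years before the first visit year through the last
    visit year, a facility reports with probability ``facility_persistence``;
    the reported modeled hazard is lognormal.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    lon0, lon1, lat0, lat1 = config.region
    y0, y1 = int(config.years[0]) - 5, int(config.years[1])
    years = np.arange(y0, y1 + 1)
    records = []
    centres = None
    if config.facility_clusters > 0:
        centres = np.column_stack([
            rng.uniform(lon0, lon1, config.facility_clusters),
            rng.uniform(lat0, lat1, config.facility_clusters),
        ])
    for agent in config.agents:
        if config.facilities_per_agent == 0:
            continue
        if centres is None:
            lons = rng.uniform(lon0, lon1, config.facilities_per_agent)
            lats = rng.uniform(lat0, lat1, config.facilities_per_agent)
        else:
            pick = rng.integers(0, len(centres), config.facilities_per_agent)
            lons = np.clip(centres[pick, 0] + rng.normal(0, config.cluster_sd_deg, config.facilities_per_agent), lon0, lon1)
            lats = np.clip(centres[pick, 1] + rng.normal(0, config.cluster_sd_deg, config.facilities_per_agent), lat0, lat1)
        for i in range(config.facilities_per_agent):
            fid = f"F_{agent}_{i:03d}"
            report = rng.random(len(years)) < config.facility_persistence
            haz = rng.lognormal(config.hazard_log_mean, config.hazard_log_sd, len(years))
            for y, rep, h in zip(years, report, haz):
                if rep:
                    records.append((fid, lons[i], lats[i], agent, int(y), float(h)))
    return pd.DataFrame(records, columns=expo.FACILITY_COLUMNS)


def _sample_categorical(rng, freqs: dict[str, float], n: int) -> np.ndarray:
    levels = sorted(freqs)
    p = np.array([freqs[k] for k in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=n, p=p)


def _candidate_batch(rng, config: SimConfig, n: int) -> pd.DataFrame:
    lon0, lon1, lat0, lat1 = config.region
    batch = pd.DataFrame({
        "lon": rng.uniform(lon0, lon1, n),
        "lat": rng.uniform(lat0, lat1, n),
        "visit_year": rng.integers(config.years[0], config.years[1] + 1, n),
        "age": np.clip(rng.normal(config.age_mean_control, config.age_sd, n), 18, 95),
        "adi_raw": rng.normal(config.adi_raw_mean, config.adi_raw_sd, n),
    })
    for var in ("sex", "race", "ethnicity", "alcohol", "tobacco"):
        batch[var] = _sample_categorical(rng, config.covariate_freqs[var], n)
    return batch


def _effect_codings(batch: pd.DataFrame, facilities: pd.DataFrame,
                    effects: dict[str, float]) -> pd.DataFrame:
    """Binary codings of the effect definitions for a candidate batch.

    presence codes as nonzero; count as >=2; idw as above the batch median of
    positives (the analysis-time cut is the cohort median, so idw effects are
    only approximately recovered — defaults plant effects on presence).
    """
    if not effects:
        return pd.DataFrame(index=batch.index)
    defs = [ExposureDefinition.from_id(k) for k in effects]
    tmp = batch.copy()
    tmp["participant_id"] = np.arange(len(batch))
    tmp["case"] = 0
    mat = expo.compute_exposure_matrix(tmp, facilities, defs)
    coded = {}
    for d in defs:
        x = mat.raw[d.id].to_numpy(float)
        if d.metric == "presence":
            coded[d.id] = (x > 0).astype(float)
        elif d.metric == "count":
            coded[d.id] = (x >= 2).astype(float)
        else:
            pos = x[x > 0]
            cut = np.median(pos) if pos.size else np.inf
            coded[d.id] = (x > cut).astype(float)
    return pd.DataFrame(coded, index=batch.index)


def _confounder_term(batch: pd.DataFrame, config: SimConfig) -> np.ndarray:
    lp = np.zeros(len(batch))
    conf = dict(config.confounder_log_or)
    # exponential-tilting age coefficient reproducing the configured case/control
    # age-mean gap under a Gaussian age distribution, unless overridden
    if "age" not in conf and config.age_mean_case != config.age_mean_control:
        conf["age"] = (config.age_mean_case - config.age_mean_control) / config.age_sd**2 * 10.0
    for key, lor in conf.items():
        if key == "age":
            lp += lor * (batch["age"].to_numpy() - 50.0) / 10.0
        elif key == "adi_std":
            lp += lor * (batch["adi_raw"].to_numpy() - config.adi_raw_mean) / config.adi_raw_sd
        elif "=" in key:
            var, level = key.split("=", 1)
            lp += lor * (batch[var].to_numpy() == level).astype(float)
        else:
            raise ValueError(f"unknown confounder key {key!r}")
    return lp


def generate_participants(
    config: SimConfig, facilities: pd.DataFrame
) -> tuple[pd.DataFrame, SimTruth]:
    """Accrue exactly n_cases cases and n_controls controls.

    Candidates are drawn in batches; each candidate's case probability is
    logistic(baseline_logit + sum of true effects on binary exposure codings
    + confounder terms). Accrual stops when both targets are met; exceeding
    ``max_candidates`` raises :class:`SimulationError`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    effects = config.resolved_effects()
    kept: list[pd.DataFrame] = []
    n_case = n_ctrl = 0
    drawn = 0
    while n_case < config.n_cases or n_ctrl < config.n_controls:
        if drawn >= config.max_candidates:
            raise SimulationError(
                f"accrued {n_case}/{config.n_cases} cases and "
                f"{n_ctrl}/{config.n_controls} controls after {drawn} candidates"
            )
        m = min(config.batch_size, config.max_candidates - drawn)
        batch = _candidate_batch(rng, config, m)
        drawn += m
        codings = _effect_codings(batch, facilities, effects)
        lp = config.baseline_logit + _confounder_term(batch, config)
        for col, lor in effects.items():
            lp = lp + lor * codings[col].to_numpy()
        p = 1.0 / (1.0 + np.exp(-lp))
        is_case = rng.random(m) < p
        batch["case"] = is_case.astype(int)
        batch["_lp"] = lp
        need_case = config.n_cases - n_case
        need_ctrl = config.n_controls - n_ctrl
        take = pd.concat([
            batch[batch["case"] == 1].iloc[:need_case],
            batch[batch["case"] == 0].iloc[:need_ctrl],
        ])
        n_case += int(take["case"].sum())
        n_ctrl += int((1 - take["case"]).sum())
        kept.append(take)

    cohort = pd.concat(kept, ignore_index=True)
    cohort = cohort.sort_values("case", ascending=False, kind="stable").reset_index(drop=True)
    cohort["participant_id"] = [f"P{i:06d}" for i in range(len(cohort))]
    cohort["cancer_type"] = np.where(cohort["case"] == 1, config.cancer_type, "none")
    cohort["adi_std"] = standardize_adi(cohort["adi_raw"].to_numpy())

    participants = cohort[expo.PARTICIPANT_COLUMNS].copy()
    grid = enumerate_grid(config.agents)
    truth_mat = expo.compute_exposure_matrix(participants, facilities, grid)
    truth = SimTruth(
        exposures=truth_mat.raw,
        linear_predictor=pd.Series(cohort["_lp"].to_numpy(), index=truth_mat.raw.index, name="lp"),
        case=pd.Series(cohort["case"].to_numpy(int), index=truth_mat.raw.index, name="case"),
        effects=effects,
        config=config,
    )
    return participants, truth


def simulate(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Convenience wrapper: facilities + participants + truth in one call."""
    facilities = generate_facilities(config)
    participants, truth = generate_participants(config, facilities)
    return facilities, participants, truth
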