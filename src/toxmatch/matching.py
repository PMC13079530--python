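"""Three matched case-control designs: nearest-neighbor, exact, optimal.

Nearest-neighbor and exact matching use age, sex, race and visit year;
optimal matching additionally uses alcohol, tobacco and the standardized
deprivation index (matching on them so the regression model need not adjust
for them). Matching is always 1:k without replacement. Distances for the
nearest-neighbor and optimal methods combine standardized continuous
differences with a large fixed penalty per mismatched categorical variable,
which enforces categorical agreement whenever an agreeing control remains.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

log = logging.getLogger(__name__)

CONTINUOUS_VARS = {"age", "visit_year", "adi_std"}
CATEGORICAL_VARS = {"sex", "race", "ethnicity", "alcohol", "tobacco"}
CATEGORICAL_PENALTY = 1000.0

DEFAULT_VARIABLES = {
    "nearest_neighbor": ("age", "sex", "race", "visit_year"),
    "exact": ("age", "sex", "race", "visit_year"),
    "optimal": ("age", "sex", "race", "visit_year", "alcohol", "tobacco", "adi_std"),
}


class MatchingError(RuntimeError):
    pass


@dataclass
class MatchSpec:
    """Specification of one matching run."""

    method: str
    variables: tuple[str, ...] = ()
    ratio: int = 4
    caliper: float | None = None
    age_bin_width: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in DEFAULT_VARIABLES:
            raise ValueError(f"unknown matching method {self.method!r}")
        if not self.variables:
            self.variables = DEFAULT_VARIABLES[self.method]
        if self.ratio < 1:
            raise ValueError("ratio (controls per case) must be >= 1")
        unknown = set(self.variables) - CONTINUOUS_VARS - CATEGORICAL_VARS
        if unknown:
            raise ValueError(f"unknown matching variables: {sorted(unknown)}")


@dataclass
class MatchedSet:
    set_id: str
    case_id: str
    control_ids: list[str]
    method: str


def _scales(participants: pd.DataFrame, variables) -> dict[str, float]:
    """Pre-match within-dataset SDs used to standardize continuous variables."""
    scales = {}
    for v in variables:
        if v in CONTINUOUS_VARS:
            sd = float(participants[v].astype(float).std(ddof=1))
            if not np.isfinite(sd) or sd == 0:
                sd = 1.0
            scales[v] = sd
    return scales


def match_distance(case: pd.Series, control: pd.Series, spec: MatchSpec,
                   scales: dict[str, float] | None = None) -> float:
    """Composite distance: sqrt of summed squared standardized continuous
    differences, plus 1000 per mismatched categorical variable."""
    if spec.method == "exact":
        raise ValueError("exact matching does not use a distance")
    sq = 0.0
    penalty = 0.0
    for v in spec.variables:
        if v in CONTINUOUS_VARS:
            s = (scales or {}).get(v, 1.0)
            a, b = float(case[v]), float(control[v])
            if not (np.isfinite(a) and np.isfinite(b)):
                raise ValueError(f"missing continuous matching value for {v}")
            sq += ((a - b) / s) ** 2
        else:
            if str(case[v]) != str(control[v]):
                penalty += CATEGORICAL_PENALTY
    return float(np.sqrt(sq) + penalty)


def distance_matrix(cases: pd.DataFrame, controls: pd.DataFrame,
                    spec: MatchSpec, scales: dict[str, float]) -> np.ndarray:
    """Vectorized case x control matrix of :func:`match_distance`."""
    sq = np.zeros((len(cases), len(controls)))
    pen = np.zeros_like(sq)
    for v in spec.variables:
        if v in CONTINUOUS_VARS:
            a = cases[v].to_numpy(float)[:, None]
            b = controls[v].to_numpy(float)[None, :]
            sq += ((a - b) / scales.get(v, 1.0)) ** 2
        else:
            a = cases[v].astype(str).to_numpy()[:, None]
            b = controls[v].astype(str).to_numpy()[None, :]
            pen += np.where(a != b, CATEGORICAL_PENALTY, 0.0)
    return np.sqrt(sq) + pen


def _split(participants: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    cases = participants[participants["case"] == 1].reset_index(drop=True)
    controls = participants[participants["case"] == 0].reset_index(drop=True)
    if cases.empty or controls.empty:
        raise MatchingError("need at least one case and one control")
    return cases, controls


def nearest_neighbor_match(participants: pd.DataFrame, spec: MatchSpec) -> list[MatchedSet]:
    """Greedy without-replacement matching.

    Cases are processed in descending age (ties by id); each takes its k
    nearest unused controls, control-id tie-break, honoring the caliper.
    """
    cases, controls = _split(participants)
    scales = _scales(participants, spec.variables)
    dist = distance_matrix(cases, controls, spec, scales)
    order = sorted(range(len(cases)),
                   key=lambda i: (-float(cases["age"].iloc[i]), str(cases["participant_id"].iloc[i])))
    ctrl_ids = controls["participant_id"].astype(str).to_numpy()
    used = np.zeros(len(controls), dtype=bool)
    sets: list[MatchedSet] = []
    for n, i in enumerate(order):
        avail = ~used
        if spec.caliper is not None:
            avail &= dist[i] <= spec.caliper
        idx = np.flatnonzero(avail)
        if idx.size == 0:
            warnings.warn(f"case {cases['participant_id'].iloc[i]} has no admissible "
                          "controls and was dropped", stacklevel=2)
            continue
        ranked = idx[np.lexsort((ctrl_ids[idx], dist[i, idx]))][: spec.ratio]
        if ranked.size < spec.ratio:
            warnings.warn(f"case {cases['participant_id'].iloc[i]} matched to only "
                          f"{ranked.size} of {spec.ratio} controls", stacklevel=2)
        used[ranked] = True
        sets.append(MatchedSet(
            set_id=f"nn_{n:05d}",
            case_id=str(cases["participant_id"].iloc[i]),
            control_ids=sorted(ctrl_ids[ranked]),
            method="nearest_neighbor",
        ))
    return sets


def _exact_key(row: pd.Series, spec: MatchSpec):
    key = []
    for v in spec.variables:
        if v == "age":
            key.append(int(np.floor(float(row[v]) / spec.age_bin_width)))
        elif v in CONTINUOUS_VARS:
            key.append(row[v])
        else:
            key.append(str(row[v]))
    return tuple(key)


def exact_match(participants: pd.DataFrame, spec: MatchSpec) -> list[MatchedSet]:
    """Exact matching on the joint key (age binned to ``age_bin_width``).

    Within each stratum, controls are dealt round-robin (seeded shuffle of
    both cases and controls) to that stratum's cases, up to k per case, so
    each emitted set contains exactly one case.
    """
    cases, controls = _split(participants)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 11]))
    case_keys = cases.apply(_exact_key, axis=1, args=(spec,))
    ctrl_keys = controls.apply(_exact_key, axis=1, args=(spec,))
    ctrl_by_key: dict = {}
    for cid, key in zip(controls["participant_id"].astype(str), ctrl_keys):
        ctrl_by_key.setdefault(key, []).append(cid)
    sets: list[MatchedSet] = []
    n_dropped = 0
    strata = {}
    for cid, key in zip(cases["participant_id"].astype(str), case_keys):
        strata.setdefault(key, []).append(cid)
    for key in sorted(strata, key=str):
        case_ids = sorted(strata[key])
        pool = sorted(ctrl_by_key.get(key, []))
        if not pool:
            n_dropped += len(case_ids)
            log.info("stratum %s: %d case(s) dropped (no controls)", key, len(case_ids))
            continue
        rng.shuffle(case_ids)
        rng.shuffle(pool)
        assigned: dict[str, list[str]] = {c: [] for c in case_ids}
        slot = 0
        for ctrl in pool:
            # deal to the next case that still has room; stop when all full
            placed = False
            for _ in range(len(case_ids)):
                cand = case_ids[slot % len(case_ids)]
                slot += 1
                if len(assigned[cand]) < spec.ratio:
                    assigned[cand].append(ctrl)
                    placed = True
                    break
            if not placed:
                break
        for cand in case_ids:
            if assigned[cand]:
                sets.append(MatchedSet(
                    set_id="", case_id=cand,
                    control_ids=sorted(assigned[cand]), method="exact",
                ))
            else:
                n_dropped += 1
    if n_dropped:
        warnings.warn(f"exact matching dropped {n_dropped} case(s) with no "
                      "stratum controls", stacklevel=2)
    if not sets:
        raise MatchingError("no stratum contained both a case and a control")
    sets.sort(key=lambda s: s.case_id)
    for n, s in enumerate(sets):
        s.set_id = f"ex_{n:05d}"
    return sets


def optimal_match(participants: pd.DataFrame, spec: MatchSpec) -> list[MatchedSet]:
    """Globally minimum-total-cost 1:k assignment without replacement.

    Each case is replicated k times and the rectangular assignment problem is
    solved exactly; when controls < k * cases this reduces to the
    maximum-cardinality minimum-cost assignment (warned)."""
    cases, controls = _split(participants)
    scales = _scales(participants, spec.variables)
    dist = distance_matrix(cases, controls, spec, scales)
    k = spec.ratio
    if len(controls) < k * len(cases):
        warnings.warn("fewer controls than ratio * cases: some sets will be "
                      "partial (max-cardinality min-cost assignment)", stacklevel=2)
    cost = np.repeat(dist, k, axis=0)
    rows, cols = linear_sum_assignment(cost if cost.shape[0] <= cost.shape[1] else cost.T)
    if cost.shape[0] > cost.shape[1]:
        rows, cols = cols, rows
    ctrl_ids = controls["participant_id"].astype(str).to_numpy()
    assigned: dict[int, list[str]] = {}
    for r, c in zip(rows, cols):
        assigned.setdefault(r // k, []).append(ctrl_ids[c])
    sets = []
    order = sorted(assigned, key=lambda i: str(cases["participant_id"].iloc[i]))
    for n, i in enumerate(order):
        sets.append(MatchedSet(
            set_id=f"op_{n:05d}",
            case_id=str(cases["participant_id"].iloc[i]),
            control_ids=sorted(assigned[i]),
            method="optimal",
        ))
    return sets


def match(participants: pd.DataFrame, spec: MatchSpec) -> list[MatchedSet]:
    """Dispatch on ``spec.method``."""
    fn = {"nearest_neighbor": nearest_neighbor_match,
          "exact": exact_match,
          "optimal": optimal_match}[spec.method]
    return fn(participants, spec)


def total_cost(sets: list[MatchedSet], participants: pd.DataFrame, spec: MatchSpec) -> float:
    """Sum of case-control distances over all matched pairs (diagnostic)."""
    scales = _scales(participants, spec.variables)
    idx = participants.set_index(participants["participant_id"].astype(str))
    tot = 0.0
    for s in sets:
        for cid in s.control_ids:
            tot += match_distance(idx.loc[s.case_id], idx.loc[cid], spec, scales)
    return tot


def sets_to_frame(sets: list[MatchedSet]) -> pd.DataFrame:
    """Long format: set_id, role, participant_id."""
    rows = []
    for s in sets:
        rows.append({"set_id": s.set_id, "role": "case", "participant_id": s.case_id})
        for cid in s.control_ids:
            rows.append({"set_id": s.set_id, "role": "control", "participant_id": cid})
    return pd.DataFrame(rows, columns=["set_id", "role", "participant_id"])


def frame_to_sets(frame: pd.DataFrame, method: str) -> list[MatchedSet]:
    sets = []
    for sid, grp in frame.groupby("set_id", sort=True):
        case_ids = grp.loc[grp["role"] == "case", "participant_id"].tolist()
        if len(case_ids) != 1:
            raise MatchingError(f"set {sid} has {len(case_ids)} cases")
        sets.append(MatchedSet(
            set_id=str(sid), case_id=str(case_ids[0]),
            control_ids=sorted(grp.loc[grp["role"] == "control", "participant_id"].astype(str)),
            method=method,
        ))
    return sets


def balance_report(sets: list[MatchedSet], participants: pd.DataFrame,
                   spec: MatchSpec, adequate: float = 0.1) -> pd.DataFrame:
    """Standardized mean differences (continuous) and per-category proportion
    differences (categorical) before and after matching.

    SMD = (mean_case - mean_control) / pooled pre-match SD; after-matching
    values use the matched sample but the same pre-match SDs. |SMD| <= 0.1 is
    flagged adequate (reported, not enforced).
    """
    if not sets:
        raise MatchingError("empty matched data")
    pre_cases, pre_controls = _split(participants)
    idx = participants.set_index(participants["participant_id"].astype(str))
    post_case_ids = [s.case_id for s in sets]
    post_ctrl_ids = [c for s in sets for c in s.control_ids]
    post_cases = idx.loc[post_case_ids]
    post_controls = idx.loc[post_ctrl_ids]

    def smd(cs, ct, v, pooled_sd):
        diff = float(cs[v].mean()) - float(ct[v].mean())
        if pooled_sd == 0:
            return 0.0 if diff == 0 else np.inf
        return diff / pooled_sd

    rows = []
    for v in spec.variables:
        if v in CONTINUOUS_VARS:
            pooled = np.sqrt((pre_cases[v].std(ddof=1) ** 2 + pre_controls[v].std(ddof=1) ** 2) / 2.0)
            pooled = float(pooled) if np.isfinite(pooled) else 0.0
            pre = smd(pre_cases, pre_controls, v, pooled)
            post = smd(post_cases, post_controls, v, pooled)
            rows.append({"variable": v, "level": "", "type": "continuous",
                         "pre": pre, "post": post, "adequate": abs(post) <= adequate})
        else:
            levels = sorted(participants[v].astype(str).unique())
            for lev in levels:
                pre = float((pre_cases[v].astype(str) == lev).mean()) - \
                    float((pre_controls[v].astype(str) == lev).mean())
                post = float((post_cases[v].astype(str) == lev).mean()) - \
                    float((post_controls[v].astype(str) == lev).mean())
                rows.append({"variable": v, "level": lev, "type": "categorical",
                             "pre": pre, "post": post, "adequate": abs(post) <= adequate})
    out = pd.DataFrame(rows)
    out.attrs["n_cases_matched"] = len(sets)
    out.attrs["n_cases_unmatched"] = len(pre_cases) - len(sets)
    return out
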