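"""End-to-end orchestration: simulate -> expose -> match -> fit -> infer.

Each stage persists plain CSV intermediates so it can be re-run in
isolation, and a JSON manifest records the configuration echo, seeds, row
counts and per-stage wall time. Identical configuration yields byte-identical
outputs. Breast-cancer runs restrict to female participants; the
never-smoker sensitivity analysis restricts both cases and the control pool
to tobacco == 'never' before matching.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import exposure as expo
from . import inference, matching, synth
from .clr import CLRDesign, fit_clr, wald_test
from .exposure import ExposureDefinition
from .matching import MatchSpec

log = logging.getLogger(__name__)

METHODS = ("nearest_neighbor", "exact", "optimal")
ADJUST_BY_METHOD = {
    "nearest_neighbor": ("alcohol", "tobacco", "adi_std"),
    "exact": ("alcohol", "tobacco", "adi_std"),
    "optimal": (),
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Full configuration of one pipeline run.

    Exactly one of ``sim`` (synthetic mode) or ``facilities_path`` +
    ``participants_path`` (external-table mode) must be provided.
    """

    out_dir: str = "toxmatch_run"
    seed: int = 0
    sim: synth.SimConfig | None = None
    facilities_path: str | None = None
    participants_path: str | None = None
    cancer_types: tuple[str, ...] = ("breast",)
    buffers_km: tuple[float, ...] = expo.BUFFERS_KM
    lags_years: tuple[int, ...] = expo.LAGS_YEARS
    ratio: int = 4
    age_bin_width: float = 5.0
    caliper: float | None = None
    never_smoker_only: bool = False
    min_exposed: int = expo.PREVALENCE_MIN_EXPOSED
    idw_power: float = 1.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        synthetic = self.sim is not None
        external = self.facilities_path is not None or self.participants_path is not None
        if synthetic and external:
            raise ValueError("synthetic mode and external-table mode are mutually exclusive")
        if not synthetic and not (self.facilities_path and self.participants_path):
            raise ValueError("provide either a SimConfig or both table paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            simraw = dict(raw.pop("sim"))
            for key in ("region", "years", "agents"):
                if key in simraw and isinstance(simraw[key], list):
                    simraw[key] = tuple(simraw[key])
            raw["sim"] = synth.SimConfig(**simraw)
        for key in ("cancer_types", "buffers_km", "lags_years"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class InputReport:
    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_inputs(facilities: pd.DataFrame, participants: pd.DataFrame) -> InputReport:
    """Structural checks on the two input tables.

    Fatal: coordinate-range violations, duplicate keys, unknown category
    levels, negative hazard. Warning: visit years whose lag windows fall
    partly before the facility reporting span.
    """
    rep = InputReport()
    for name, df, cols in (("facilities", facilities, expo.FACILITY_COLUMNS),
                           ("participants", participants, expo.PARTICIPANT_COLUMNS)):
        missing = set(cols) - set(df.columns)
        if missing:
            rep.fatal.append(f"{name}: missing columns {sorted(missing)}")
    if rep.fatal:
        return rep
    for name, df in (("facilities", facilities), ("participants", participants)):
        if (df["lat"].abs() > 90).any() or (df["lon"].abs() > 180).any():
            rep.fatal.append(f"{name}: coordinates outside valid lon/lat ranges")
    if facilities.duplicated(["facility_id", "agent", "year"]).any():
        rep.fatal.append("facilities: duplicate (facility_id, agent, year) keys")
    if participants["participant_id"].duplicated().any():
        rep.fatal.append("participants: duplicate participant_id")
    if (facilities["modeled_hazard"] < 0).any():
        rep.fatal.append("facilities: negative modeled_hazard")
    for var in ("alcohol", "tobacco"):
        bad = set(participants[var].astype(str).unique()) - {"current", "past", "never", "unknown"}
        if bad:
            rep.fatal.append(f"participants: unknown {var} levels {sorted(bad)}")
    if not set(participants["cancer_type"].astype(str).unique()) <= {"breast", "lung", "none"}:
        rep.fatal.append("participants: unknown cancer_type levels")
    if ((participants["case"] == 1) & (participants["cancer_type"] == "none")).any():
        rep.fatal.append("participants: case=1 with cancer_type 'none'")
    y_min = int(facilities["year"].min())
    if (participants["visit_year"] < y_min + 1).any():
        rep.warnings.append("some visit years precede the facility reporting span + 1 "
                            "(lag windows partially empty)")
    if (participants["visit_year"] > int(facilities["year"].max()) + 5).any():
        rep.warnings.append("some visit years are > 5 years after the last facility report")
    return rep


def analysis_subset(participants: pd.DataFrame, cancer: str,
                    never_smoker_only: bool = False) -> pd.DataFrame:
    """Cases of one cancer plus the shared control pool.

    Breast runs are female-only (cases and controls); the never-smoker flag
    restricts both cases and controls to tobacco == 'never'.
    """
    cases = participants[(participants["case"] == 1)
                         & (participants["cancer_type"] == cancer)]
    controls = participants[participants["case"] == 0]
    sub = pd.concat([cases, controls], ignore_index=True)
    if cancer == "breast":
        sub = sub[sub["sex"] == "female"]
    if never_smoker_only:
        sub = sub[sub["tobacco"] == "never"]
    return sub.reset_index(drop=True)


def _design_skeleton(sets, participants, adjust):
    """Per-method design pieces reused across every exposure definition."""
    part = participants.set_index(participants["participant_id"].astype(str))
    pids, y, sizes = [], [], []
    for s in sets:
        members = [s.case_id] + list(s.control_ids)
        sizes.append(len(members))
        pids.extend(members)
        y.extend([1] + [0] * (len(members) - 1))
    rows = part.loc[pids]
    cols, mats = [], []
    for a in adjust:
        if a in ("alcohol", "tobacco"):
            for lev in ("current", "past", "unknown"):
                cols.append(f"{a}_{lev}")
                mats.append((rows[a].astype(str) == lev).to_numpy(float))
        else:
            cols.append(a)
            mats.append(rows[a].to_numpy(float))
    adj = np.column_stack(mats) if mats else np.empty((len(pids), 0))
    y = np.asarray(y, int)
    sizes = np.asarray(sizes, int)
    # drop adjustment columns constant within every set (inestimable)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    keep = []
    for j in range(adj.shape[1]):
        mn = np.minimum.reduceat(adj[:, j], starts)
        mx = np.maximum.reduceat(adj[:, j], starts)
        if np.any(mx > mn):
            keep.append(j)
    dropped = [c for j, c in enumerate(cols) if j not in keep]
    if dropped:
        log.info("dropping set-constant adjustment covariates: %s", dropped)
    return pids, y, sizes, adj[:, keep], [cols[j] for j in keep]


def fit_all(matrix: expo.ExposureMatrix, retained, sets_by_method,
            participants: pd.DataFrame, cancer: str) -> pd.DataFrame:
    """Conditional-logistic fits for every retained definition x method."""
    out = []
    for method, sets in sets_by_method.items():
        adjust = ADJUST_BY_METHOD[method]
        pids, y, sizes, adj, adj_cols = _design_skeleton(sets, participants, adjust)
        for defn in retained:
            coding = matrix.coding[defn.id]
            x = coding.loc[pids].to_numpy(float)
            design = CLRDesign(X=np.column_stack([x, adj]), y=y, set_sizes=sizes,
                               columns=["exposure"] + adj_cols)
            fit = fit_clr(design)
            row = {
                "definition_id": defn.id, "agent": defn.agent, "metric": defn.metric,
                "buffer_km": defn.buffer_km, "lag_years": defn.lag_years,
                "method": method, "cancer": cancer,
                "n_sets": fit.n_sets, "n_informative": fit.n_informative,
                "status": fit.status if fit.evaluable else "non_evaluable",
            }
            if fit.evaluable:
                z, p, ci = wald_test(fit, "exposure")
                row.update(beta=fit.coef("exposure"), se=float(fit.se[0]),
                           **{"or": fit.or_}, ci_low=ci[0], ci_high=ci[1], p_raw=p)
            else:
                row.update(beta=np.nan, se=np.nan, ci_low=np.nan,
                           ci_high=np.nan, p_raw=np.nan, **{"or": np.nan})
            out.append(row)
    return pd.DataFrame(out, columns=inference.RESULT_COLUMNS)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and return the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "toxmatch_version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "stages": {},
        "counts": {},
    }
    try:
        t0 = time.perf_counter()
        if config.sim is not None:
            facilities, participants, truth = synth.simulate(config.sim)
            truth.to_json(out / "truth.json")
        else:
            facilities = pd.read_csv(config.facilities_path)
            participants = pd.read_csv(config.participants_path)
        _write_csv(facilities, out / "facilities.csv")
        _write_csv(participants, out / "participants.csv")
        manifest["stages"]["simulate"] = round(time.perf_counter() - t0, 3)
        manifest["counts"]["facility_records"] = int(len(facilities))
        manifest["counts"]["participants"] = int(len(participants))

        report = validate_inputs(facilities, participants)
        for w in report.warnings:
            log.warning("%s", w)
        if not report.ok:
            raise PipelineError("validate", "; ".join(report.fatal))

        agents = sorted(facilities["agent"].unique())
        grid = expo.enumerate_grid(agents, buffers_km=config.buffers_km,
                                   lags_years=config.lags_years)
        for cancer in config.cancer_types:
            _run_cancer(config, cancer, facilities, participants, grid, out, manifest)
    except PipelineError:
        (out / "failed").write_text("see log\n")
        raise
    except Exception as exc:  # tag unexpected failures with a stage marker
        (out / "failed").write_text(f"{exc}\n")
        raise PipelineError("run", str(exc)) from exc
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_cancer(config, cancer, facilities, participants, grid, out, manifest):
    cdir = out / cancer
    cdir.mkdir(exist_ok=True)
    sub = analysis_subset(participants, cancer, config.never_smoker_only)
    n_cases = int((sub["case"] == 1).sum())
    manifest["counts"][f"{cancer}_cases"] = n_cases
    manifest["counts"][f"{cancer}_controls"] = int((sub["case"] == 0).sum())
    if n_cases == 0:
        raise PipelineError("match", f"no {cancer} cases in the analysis subset")

    t0 = time.perf_counter()
    matrix = expo.compute_exposure_matrix(sub, facilities, grid, idw_power=config.idw_power)
    expo.dichotomize(matrix)
    retained = expo.prevalence_filter(matrix, min_exposed=config.min_exposed)
    _write_csv(matrix.raw.reset_index(), cdir / "exposures.csv")
    _write_csv(expo.definitions_table(matrix, retained), cdir / "definitions.csv")
    manifest["stages"][f"{cancer}_expose"] = round(time.perf_counter() - t0, 3)
    manifest["counts"][f"{cancer}_retained_definitions"] = len(retained)
    if not retained:
        raise PipelineError("expose", f"no definitions survive the prevalence filter for {cancer}")

    t0 = time.perf_counter()
    sets_by_method = {}
    for method in METHODS:
        spec = MatchSpec(method=method, ratio=config.ratio,
                         age_bin_width=config.age_bin_width,
                         caliper=config.caliper, seed=config.seed)
        sets = matching.match(sub, spec)
        sets_by_method[method] = sets
        _write_csv(matching.sets_to_frame(sets), cdir / f"matched_{method}.csv")
        _write_csv(matching.balance_report(sets, sub, spec), cdir / f"balance_{method}.csv")
        manifest["counts"][f"{cancer}_{method}_sets"] = len(sets)
    manifest["stages"][f"{cancer}_match"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    results = fit_all(matrix, retained, sets_by_method, sub, cancer)
    for method in METHODS:
        _write_csv(results[results["method"] == method].drop(columns=["method"]),
                   cdir / f"clr_results_{method}.csv")
    manifest["stages"][f"{cancer}_fit"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    adjusted = inference.bonferroni_adjust(results)
    cons = inference.consensus(adjusted)
    summary = inference.agent_summary(adjusted)
    _write_csv(adjusted, cdir / "clr_results_adjusted.csv")
    _write_csv(cons, cdir / "consensus.csv")
    _write_csv(summary, cdir / "agent_summary.csv")
    for method in METHODS:
        table, meta = inference.volcano_export(adjusted, method)
        table.attrs.update(meta)
        head = pd.DataFrame([meta])
        _write_csv(table, cdir / f"volcano_{method}.csv")
        _write_csv(head, cdir / f"volcano_{method}_meta.csv")
    manifest["stages"][f"{cancer}_infer"] = round(time.perf_counter() - t0, 3)
    manifest["counts"][f"{cancer}_overall_significant"] = int(cons["overall_significant"].sum())


def _config_echo(config: RunConfig) -> dict:
    echo = asdict(config)
    if config.sim is not None:
        echo["sim"] = {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config.sim).items()}
    for k, v in list(echo.items()):
        if isinstance(v, tuple):
            echo[k] = list(v)
    return echo
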