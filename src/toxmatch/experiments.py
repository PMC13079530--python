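"""Validation studies run against known synthetic truth.

Three repeated-simulation studies characterise the pipeline:

* ``recovery_study`` — conditional-logistic parameter recovery on matched
  sets generated directly from the conditional model (one case per set drawn
  with probability proportional to exp(beta * exposure)), measuring bias of
  the log odds ratio and Wald 95% CI coverage.
* ``null_error_study`` — the full pipeline (simulate, exposure grid, three
  matchings, CLR, Bonferroni + consensus) under a fully null generator; the
  per-agent proportion of replicates with any overall-significant definition
  estimates the family-wise error of the consensus rule.
* ``power_study`` — the same pipeline with one strong planted presence
  effect, measuring how often the consensus rule detects it and how the
  planted agent's summary percentage compares with the null agents'.

Replicate scale (hundreds of cases, a compact ~120 x 110 km study region,
two agents) is chosen so repeated studies remain cheap while every stage of
the pipeline is exercised; the generator's covariate structure follows the
package defaults.
"""

from __future__ import annotations

import numpy as np

from . import exposure as expo
from .clr import CLRDesign, fit_clr, wald_test
from .inference import agent_summary, bonferroni_adjust, consensus
from .matching import MatchSpec, match
from .pipeline import METHODS, analysis_subset, fit_all
from .synth import SimConfig, simulate

#: compact study region used by the repeated-simulation studies
STUDY_REGION = (-78.0, -76.8, 37.0, 38.0)
STUDY_AGENTS = ("chromium", "benzene")
PLANTED_DEFINITION = "chromium|presence|20|5"


def simulate_conditional_sets(n_sets: int, k: int, beta: float,
                              p_exposed: float, rng: np.random.Generator) -> CLRDesign:
    """Matched sets drawn directly from the conditional likelihood.

    Each set has 1 + k members with iid Bernoulli(p_exposed) binary
    exposures; the case is the member j drawn with probability proportional
    to exp(beta * x_j). This is the exact generative counterpart of the
    conditional logistic model, so beta is recovered without approximation.
    """
    size = k + 1
    x = (rng.random((n_sets, size)) < p_exposed).astype(float)
    w = np.exp(beta * x)
    p = w / w.sum(axis=1, keepdims=True)
    u = rng.random(n_sets)
    case_idx = (np.cumsum(p, axis=1) < u[:, None]).sum(axis=1)
    y = np.zeros((n_sets, size), int)
    y[np.arange(n_sets), case_idx] = 1
    return CLRDesign(X=x.reshape(-1, 1), y=y.reshape(-1),
                     set_sizes=np.full(n_sets, size), columns=["exposure"])


def recovery_study(n_datasets: int = 200, n_sets: int = 500, k: int = 4,
                   true_or: float = 2.0, p_exposed: float = 0.3,
                   seed: int = 0) -> dict:
    """Bias and CI coverage of the CLR estimator over repeated datasets."""
    beta0 = float(np.log(true_or))
    betas, covered = [], []
    root = np.random.SeedSequence([int(seed), 61])
    for child in root.spawn(n_datasets):
        rng = np.random.default_rng(child)
        design = simulate_conditional_sets(n_sets, k, beta0, p_exposed, rng)
        fit = fit_clr(design)
        if not fit.evaluable:
            continue
        _, _, ci = wald_test(fit, "exposure")
        betas.append(fit.coef("exposure"))
        covered.append(ci[0] <= true_or <= ci[1])
    betas = np.asarray(betas)
    return {
        "n_datasets": len(betas),
        "true_log_or": beta0,
        "mean_beta": float(betas.mean()),
        "sd_beta": float(betas.std(ddof=1)),
        "mc_se": float(betas.std(ddof=1) / np.sqrt(len(betas))),
        "bias": float(betas.mean() - beta0),
        "coverage": float(np.mean(covered)),
    }


def null_sim_config(seed: int) -> SimConfig:
    """Fully null generator: no exposure effects, shared covariate structure."""
    return SimConfig(
        seed=seed,
        region=STUDY_REGION,
        n_cases=100,
        n_controls=800,
        years=(2017, 2019),
        agents=STUDY_AGENTS,
        facilities_per_agent=10,
        facility_persistence=0.9,
        cancer_type="lung",
        true_log_or={},
    )


def power_sim_config(seed: int, true_or: float = 2.5) -> SimConfig:
    """One strong planted presence effect on chromium at 20 km / lag 5."""
    cfg = null_sim_config(seed)
    cfg.n_cases = 600
    cfg.n_controls = 3600
    cfg.true_log_or = {PLANTED_DEFINITION: float(np.log(true_or))}
    return cfg


def pipeline_replicate(sim: SimConfig, ratio: int = 4,
                       min_exposed: int = expo.PREVALENCE_MIN_EXPOSED) -> dict:
    """One full in-memory pipeline pass on a fresh synthetic cohort."""
    facilities, participants, truth = simulate(sim)
    sub = analysis_subset(participants, sim.cancer_type)
    grid = expo.enumerate_grid(sim.agents)
    matrix = expo.compute_exposure_matrix(sub, facilities, grid)
    expo.dichotomize(matrix)
    retained = expo.prevalence_filter(matrix, min_exposed=min_exposed)
    sets_by_method = {
        m: match(sub, MatchSpec(method=m, ratio=ratio, seed=sim.seed))
        for m in METHODS
    }
    results = fit_all(matrix, retained, sets_by_method, sub, sim.cancer_type)
    adjusted = bonferroni_adjust(results)
    cons = consensus(adjusted)
    summary = agent_summary(adjusted, drop_all_null=False)
    coding = matrix.coding
    is_case = matrix.case.to_numpy().astype(bool)
    exposed_cases = {c: int(coding[c].to_numpy()[is_case].sum()) for c in coding.columns}
    return {
        "adjusted": adjusted,
        "consensus": cons,
        "summary": summary,
        "n_retained": len(retained),
        "exposed_cases": exposed_cases,
    }


def null_error_study(n_seeds: int = 200, seed: int = 0) -> dict:
    """Per-agent family-wise error of the consensus rule under the null."""
    hits = {a: 0 for a in STUDY_AGENTS}
    for i in range(n_seeds):
        rep = pipeline_replicate(null_sim_config((seed * 100_003 + i) % (2**31 - 1)))
        cons = rep["consensus"]
        if cons.empty:
            continue
        agents = cons["definition_id"].str.split("|").str[0]
        for a in STUDY_AGENTS:
            if bool(cons.loc[(agents == a), "overall_significant"].any()):
                hits[a] += 1
    return {
        "n_seeds": n_seeds,
        "per_agent_fwer": {a: hits[a] / n_seeds for a in STUDY_AGENTS},
        "max_fwer": max(hits[a] / n_seeds for a in STUDY_AGENTS),
    }


def power_study(n_seeds: int = 100, seed: int = 0, true_or: float = 2.5) -> dict:
    """Detection rate of the planted definition and agent-summary contrast."""
    planted_agent = PLANTED_DEFINITION.split("|")[0]
    detected = 0
    min_exposed_cases = None
    pct = {a: [] for a in STUDY_AGENTS}
    for i in range(n_seeds):
        rep = pipeline_replicate(power_sim_config((seed * 100_003 + i) % (2**31 - 1), true_or))
        cons = rep["consensus"]
        row = cons[cons["definition_id"] == PLANTED_DEFINITION]
        if len(row) == 1 and bool(row["overall_significant"].iloc[0]) and row["direction"].iloc[0] > 0:
            detected += 1
        ec = rep["exposed_cases"].get(PLANTED_DEFINITION, 0)
        min_exposed_cases = ec if min_exposed_cases is None else min(min_exposed_cases, ec)
        summary = rep["summary"]
        for a in STUDY_AGENTS:
            vals = summary.loc[summary["agent"] == a, "pct_significant_positive"].dropna()
            pct[a].append(float(vals.mean()) if len(vals) else 0.0)
    mean_pct = {a: float(np.mean(v)) for a, v in pct.items()}
    return {
        "n_seeds": n_seeds,
        "power": detected / n_seeds,
        "min_exposed_cases": int(min_exposed_cases or 0),
        "mean_pct_by_agent": mean_pct,
        "planted_agent": planted_agent,
        "planted_exceeds_null": all(
            mean_pct[planted_agent] > mean_pct[a]
            for a in STUDY_AGENTS if a != planted_agent
        ),
    }
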