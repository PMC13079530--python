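"""Conditional logistic regression for 1:k matched case-control sets.

The conditional likelihood conditions on one case per matched set,
eliminating per-set nuisance intercepts: with covariate rows x_j for the
members of set s and the case indexed c(s),

    loglik(beta) = sum_s [ x_c(s)'beta - log sum_{j in s} exp(x_j'beta) ].

Fitting is by Newton-Raphson with step-halving on the exact score and
observed information of this likelihood. Sets whose covariate rows are all
identical carry no information (their contribution is constant in beta) and
are retained but counted separately. Perfect separation — the exposure
perfectly predicting case status within the informative sets — drives the
estimate to infinity and is flagged as non-evaluable instead of reporting a
meaningless number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

MAX_ITER = 100
SCORE_TOL = 1e-8
LOGLIK_RELTOL = 1e-12
SEPARATION_BETA = 15.0
RIDGE = 1e-8
Z975 = 1.959964

ADJUST_DUMMIES = {
    "alcohol": ("current", "past", "unknown"),  # reference: never
    "tobacco": ("current", "past", "unknown"),
}


class DesignError(ValueError):
    pass


@dataclass
class CLRDesign:
    """Stacked member rows of all matched sets.

    X has one row per set member (cases and controls); ``y`` marks the case;
    ``set_sizes`` gives the member count of each contiguous block. The first
    column of X is the exposure coding; remaining columns are adjustment
    covariates.
    """

    X: np.ndarray
    y: np.ndarray
    set_sizes: np.ndarray
    columns: list[str]
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.X)):
            raise DesignError("non-finite covariate values")
        starts = np.concatenate([[0], np.cumsum(self.set_sizes)[:-1]])
        cases_per_set = np.add.reduceat(self.y, starts)
        if not np.all(cases_per_set == 1):
            raise DesignError("every set must contain exactly one case")

    @property
    def n_sets(self) -> int:
        return len(self.set_sizes)

    @property
    def starts(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.set_sizes)[:-1]])

    def informative_mask(self) -> np.ndarray:
        """Sets in which at least one covariate column varies across members."""
        starts = self.starts
        mask = np.zeros(self.n_sets, dtype=bool)
        for j in range(self.X.shape[1]):
            col = self.X[:, j]
            mn = np.minimum.reduceat(col, starts)
            mx = np.maximum.reduceat(col, starts)
            mask |= mx > mn
        return mask


@dataclass
class CLRFit:
    beta: np.ndarray
    se: np.ndarray
    columns: list[str]
    loglik: float
    converged: bool
    status: str  # 'ok' | 'non_evaluable'
    reason: str
    n_sets: int
    n_informative: int
    n_iter: int

    @property
    def evaluable(self) -> bool:
        return self.status == "ok"

    def coef(self, name: str = None) -> float:
        i = 0 if name is None else self.columns.index(name)
        return float(self.beta[i])

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta[0]))

    @property
    def ci95(self) -> tuple[float, float]:
        return (float(np.exp(self.beta[0] - Z975 * self.se[0])),
                float(np.exp(self.beta[0] + Z975 * self.se[0])))


def build_design(
    sets,
    participants: pd.DataFrame,
    exposure_coding: pd.Series,
    adjust: tuple[str, ...] = (),
) -> CLRDesign:
    """Assemble the stacked design from matched sets.

    ``adjust`` may contain 'alcohol', 'tobacco' (dummy-coded against the
    'never' reference with 'unknown' kept as its own level) and 'adi_std'.
    Covariates constant within every set are inestimable in a conditional
    likelihood and are dropped with a warning.
    """
    part = participants.set_index(participants["participant_id"].astype(str))
    cols = ["exposure"]
    for a in adjust:
        if a in ADJUST_DUMMIES:
            cols += [f"{a}_{lev}" for lev in ADJUST_DUMMIES[a]]
        else:
            cols.append(a)
    rows, y, sizes = [], [], []
    for s in sets:
        members = [s.case_id] + list(s.control_ids)
        sizes.append(len(members))
        for i, pid in enumerate(members):
            y.append(1 if i == 0 else 0)
            p = part.loc[pid]
            row = [float(exposure_coding.loc[pid])]
            for a in adjust:
                if a in ADJUST_DUMMIES:
                    row += [1.0 if str(p[a]) == lev else 0.0 for lev in ADJUST_DUMMIES[a]]
                else:
                    row.append(float(p[a]))
            rows.append(row)
    X = np.asarray(rows, float)
    y = np.asarray(y, int)
    sizes = np.asarray(sizes, int)
    design = CLRDesign(X=X, y=y, set_sizes=sizes, columns=cols)
    # drop set-constant covariates (never the exposure column)
    starts = design.starts
    keep, dropped = [0], []
    for j in range(1, X.shape[1]):
        mn = np.minimum.reduceat(X[:, j], starts)
        mx = np.maximum.reduceat(X[:, j], starts)
        if np.any(mx > mn):
            keep.append(j)
        else:
            dropped.append(cols[j])
    if dropped:
        warnings.warn(f"dropping set-constant covariates (inestimable in a "
                      f"conditional likelihood): {dropped}", stacklevel=2)
    return CLRDesign(X=X[:, keep], y=y, set_sizes=sizes,
                     columns=[cols[j] for j in keep], dropped=dropped)


def _set_softmax(eta: np.ndarray, starts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    mx = np.maximum.reduceat(eta, starts)
    e = np.exp(eta - np.repeat(mx, sizes))
    denom = np.add.reduceat(e, starts)
    return e / np.repeat(denom, sizes)


def conditional_loglik(design: CLRDesign, beta: np.ndarray) -> float:
    """Exact conditional log-likelihood at ``beta``."""
    beta = np.asarray(beta, float)
    eta = design.X @ beta
    starts = design.starts
    mx = np.maximum.reduceat(eta, starts)
    lse = mx + np.log(np.add.reduceat(np.exp(eta - np.repeat(mx, design.set_sizes)), starts))
    return float(np.sum(eta[design.y == 1]) - np.sum(lse))


def _score_info(design: CLRDesign, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X, y = design.X, design.y
    starts, sizes = design.starts, design.set_sizes
    p = _set_softmax(X @ beta, starts, sizes)
    score = X.T @ (y - p)
    m = np.empty((design.n_sets, X.shape[1]))
    for j in range(X.shape[1]):
        m[:, j] = np.add.reduceat(p * X[:, j], starts)
    info = (X * p[:, None]).T @ X - m.T @ m
    return score, info


def fit_clr(design: CLRDesign) -> CLRFit:
    """Newton-Raphson with step-halving on the conditional likelihood.

    Convergence: max |score| < 1e-8 or relative log-likelihood change
    < 1e-12, capped at 100 iterations. |beta| > 15 on any coefficient is
    treated as separation and flagged non-evaluable.
    """
    p = design.X.shape[1]
    informative = design.informative_mask()
    n_informative = int(informative.sum())
    base = dict(columns=design.columns, n_sets=design.n_sets, n_informative=n_informative)
    if n_informative == 0:
        return CLRFit(beta=np.full(p, np.nan), se=np.full(p, np.nan),
                      loglik=np.nan, converged=False, status="non_evaluable",
                      reason="no informative sets", n_iter=0, **base)
    beta = np.zeros(p)
    ll = conditional_loglik(design, beta)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        score, info = _score_info(design, beta)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            warnings.warn("singular information matrix: ridge fallback", stacklevel=2)
            step = np.linalg.solve(info + RIDGE * np.eye(p), score)
        # step-halving: require non-decreasing log-likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = conditional_loglik(design, cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-13:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll_prev, ll = ll, ll_new
        if abs(ll - ll_prev) < LOGLIK_RELTOL * (abs(ll_prev) + 1e-30):
            converged = True
            break
    if np.any(np.abs(beta) > SEPARATION_BETA):
        return CLRFit(beta=np.full(p, np.nan), se=np.full(p, np.nan),
                      loglik=float(ll), converged=False, status="non_evaluable",
                      reason="separation (|beta| > 15)", n_iter=it, **base)
    _, info = _score_info(design, beta)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        warnings.warn("singular information at optimum: ridge fallback", stacklevel=2)
        cov = np.linalg.inv(info + RIDGE * np.eye(p))
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    if not converged:
        return CLRFit(beta=beta, se=se, loglik=float(ll), converged=False,
                      status="non_evaluable", reason="did not converge",
                      n_iter=it, **base)
    return CLRFit(beta=beta, se=se, loglik=float(ll), converged=True,
                  status="ok", reason="", n_iter=it, **base)


def wald_test(fit: CLRFit, coefficient: str = "exposure") -> tuple[float, float, tuple[float, float]]:
    """Wald z, two-sided p, and 95% CI on the odds-ratio scale."""
    if not fit.evaluable:
        raise ValueError(f"fit is not evaluable: {fit.reason}")
    i = fit.columns.index(coefficient)
    if fit.se[i] == 0:
        raise ValueError("zero standard error: Wald test not evaluable")
    z = float(fit.beta[i] / fit.se[i])
    p = float(2.0 * norm.sf(abs(z)))
    ci = (float(np.exp(fit.beta[i] - Z975 * fit.se[i])),
          float(np.exp(fit.beta[i] + Z975 * fit.se[i])))
    return z, p, ci
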