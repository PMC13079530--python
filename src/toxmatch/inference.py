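"""Multiple-comparisons adjustment and triple-matching consensus inference.

P-values are Bonferroni-adjusted within each (agent, matching method, cancer)
family, where the family size is the number of evaluable, filter-surviving
definitions for that agent. An exposure definition is declared overall
significant only when its adjusted p-value is below 0.01 under ALL THREE
matching strategies with a consistent odds-ratio direction — a deliberately
conservative rule that guards against findings peculiar to one matching
method. Agent-level summaries report the percentage of evaluable definitions
that are significant with OR > 1, and volcano exports pair the log odds
ratio with the negative log10 adjusted p-value.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

SIGNIFICANCE_LEVEL = 0.01
RESULT_COLUMNS = [
    "definition_id", "agent", "metric", "buffer_km", "lag_years", "method",
    "cancer", "n_sets", "n_informative", "beta", "se", "or", "ci_low",
    "ci_high", "p_raw", "status",
]


def bonferroni_adjust(results: pd.DataFrame) -> pd.DataFrame:
    """Adjusted p-values within (agent, method, cancer) families.

    m = number of evaluable rows of the family; p_adj = min(1, m * p_raw).
    Non-evaluable rows get p_adj = NaN and never count toward m.
    """
    out = results.copy()
    out["p_adj"] = np.nan
    out["m_tests"] = 0
    group_cols = [c for c in ("agent", "method", "cancer") if c in out.columns]
    for _, idx in out.groupby(group_cols, dropna=False).groups.items():
        sub = out.loc[idx]
        ok = sub["status"] == "ok"
        m = int(ok.sum())
        out.loc[idx, "m_tests"] = m
        if m:
            sel = sub.index[ok]
            out.loc[sel, "p_adj"] = np.minimum(1.0, m * out.loc[sel, "p_raw"])
    out["significant"] = (out["p_adj"] < SIGNIFICANCE_LEVEL).fillna(False)
    out["direction"] = np.sign(np.log(out["or"].where(out["status"] == "ok")))
    return out


def consensus(adjusted: pd.DataFrame, methods=("nearest_neighbor", "exact", "optimal")) -> pd.DataFrame:
    """Per-definition consensus across the three matched analyses.

    overall_significant requires the definition to be evaluable with
    p_adj < 0.01 in every method AND the OR direction to agree across all
    methods; definitions missing or non-evaluable in any method fail.
    """
    rows = []
    group_cols = ["definition_id"] + (["cancer"] if "cancer" in adjusted.columns else [])
    for key, grp in adjusted.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(group_cols, key))
        per = {m: grp[grp["method"] == m] for m in methods}
        all_present = all(len(per[m]) == 1 and per[m]["status"].iloc[0] == "ok" for m in methods)
        for m in methods:
            if len(per[m]) == 1:
                rec[f"or_{m}"] = float(per[m]["or"].iloc[0])
                rec[f"p_adj_{m}"] = float(per[m]["p_adj"].iloc[0])
            else:
                rec[f"or_{m}"], rec[f"p_adj_{m}"] = np.nan, np.nan
        if all_present:
            sig = all(per[m]["p_adj"].iloc[0] < SIGNIFICANCE_LEVEL for m in methods)
            dirs = {float(per[m]["direction"].iloc[0]) for m in methods}
            consistent = len(dirs) == 1 and 0.0 not in dirs
            rec["direction_consistent"] = bool(consistent)
            rec["overall_significant"] = bool(sig and consistent)
            rec["direction"] = dirs.pop() if consistent else 0.0
        else:
            rec["direction_consistent"] = False
            rec["overall_significant"] = False
            rec["direction"] = 0.0
        rows.append(rec)
    return pd.DataFrame(rows)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def agent_summary(adjusted: pd.DataFrame, drop_all_null: bool = True) -> pd.DataFrame:
    """Percentage of evaluable definitions per (agent, method[, cancer]) that
    are significant with OR > 1, rounded half-up to integer percent.

    Agents with no significant result under any method/cancer are omitted
    (mirroring the convention of dropping all-null rows from the summary
    table). Zero evaluable definitions reports a missing percentage.
    """
    group_cols = [c for c in ("agent", "method", "cancer") if c in adjusted.columns]
    rows = []
    for key, grp in adjusted.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(group_cols, key))
        ok = grp[grp["status"] == "ok"]
        n_eval = len(ok)
        n_sig_pos = int((ok["significant"] & (ok["or"] > 1.0)).sum())
        rec["n_evaluable"] = n_eval
        rec["n_significant_positive"] = n_sig_pos
        rec["pct_significant_positive"] = (
            _round_half_up(100.0 * n_sig_pos / n_eval) if n_eval else np.nan
        )
        rows.append(rec)
    out = pd.DataFrame(rows)
    if drop_all_null and not out.empty:
        keep = out.groupby("agent")["n_significant_positive"].transform("sum") > 0
        out = out[keep].reset_index(drop=True)
    return out


def volcano_export(adjusted: pd.DataFrame, method: str) -> tuple[pd.DataFrame, dict]:
    """Volcano-plot coordinates for one matched analysis.

    x = natural log OR, y = -log10(adjusted p); metadata carries the
    significance threshold line at -log10(0.01) and the axis bases.
    Non-evaluable rows are excluded; p_adj is capped at 1 so y >= 0.
    """
    sub = adjusted[(adjusted["method"] == method) & (adjusted["status"] == "ok")].copy()
    p = np.minimum(1.0, sub["p_adj"].to_numpy(float))
    table = pd.DataFrame({
        "definition_id": sub["definition_id"].to_numpy(),
        "x": np.log(sub["or"].to_numpy(float)),
        "y": -np.log10(p),
        "significant": sub["significant"].to_numpy(bool),
    })
    meta = {
        "method": method,
        "y_threshold": -math.log10(SIGNIFICANCE_LEVEL),
        "x_base": "e",
        "y_base": 10,
    }
    return table, meta


def plot_volcano(table: pd.DataFrame, meta: dict, path) -> None:
    """Render a volcano plot (dashed significance threshold, zero-effect
    line); requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = np.where(table["significant"], "crimson", "gray")
    ax.scatter(table["x"], table["y"], s=12, c=colors, alpha=0.7)
    ax.axhline(meta["y_threshold"], color="red", linestyle="--", linewidth=1)
    ax.axvline(0.0, color="red", linewidth=1)
    ax.set_xlabel("log odds ratio")
    ax.set_ylabel("-log10 adjusted p")
    ax.set_title(meta.get("method", ""))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
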