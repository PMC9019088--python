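"""Paired parental/resistant differential-sensitivity screening.

Compares per-compound dose-response summaries between a resistant line
(kept under its maintenance inhibitor) and its parental line, computes
the averaged mean-viability difference (Avg Delta MV) and the absolute
IC50 log2 fold change, and calls hits by threshold: a compound is a
Delta-MV hit when Avg Delta MV <= -0.10 (boundary inclusive) and an
IC50-FC hit when log2(IC50_resistant / IC50_parental) <= -1.  Negative
values of either statistic flag compounds to which the resistant line is
*more* sensitive than the parental line — candidate resistance drivers
or combination partners.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DELTA_MV_THRESHOLD",
    "IC50_FC_THRESHOLD",
    "delta_mv",
    "ic50_log2fc",
    "build_screen_table",
    "call_hits",
    "plot_hits",
]

DELTA_MV_THRESHOLD = -0.10
IC50_FC_THRESHOLD = -1.0


def delta_mv(mv_resistant_runs, mv_parental_runs) -> float:
    """Average over paired runs of (MV_resistant - MV_parental)."""
    r = np.atleast_1d(np.asarray(mv_resistant_runs, dtype=float))
    p = np.atleast_1d(np.asarray(mv_parental_runs, dtype=float))
    if r.shape != p.shape:
        raise ValueError(
            f"unpaired runs: {r.shape[0]} resistant vs {p.shape[0]} parental")
    if r.size == 0:
        raise ValueError("need at least one paired run")
    return float(np.mean(r - p))


def ic50_log2fc(ic50_resistant, ic50_parental) -> float | None:
    """log2(IC50_resistant / IC50_parental); None when either is not reached.

    Accepts floats (NaN/None meaning not reached) or AbsoluteIC50 objects.
    A compound whose curve never reaches 50% inhibition in one line has
    no defined fold change and is excluded from FC-based ranking.
    """
    vals = []
    for x in (ic50_resistant, ic50_parental):
        if hasattr(x, "value"):
            x = x.value
        if x is None or (isinstance(x, float) and np.isnan(x)):
            return None
        x = float(x)
        if x <= 0:
            raise ValueError(f"IC50 must be positive, got {x}")
        vals.append(x)
    return float(np.log2(vals[0] / vals[1]))


def build_screen_table(parental_fits: pd.DataFrame,
                       resistant_fits: pd.DataFrame,
                       annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Join per-run fit tables for the two lines into per-compound records.

    Each fit table is the output of :func:`resistx.doseresp.fit_table`
    and may contain multiple biological-replicate runs per compound (a
    ``run`` column; absent means a single run).  MV differences are
    averaged across paired runs; IC50 fold changes are averaged on the
    log2 scale.  Compounds unconverged in either line in any run get NaN
    statistics and ``fit_ok=False``.
    """
    par = parental_fits.copy()
    res = resistant_fits.copy()
    for df in (par, res):
        if "run" not in df.columns:
            df["run"] = 1

    merged = par.merge(res, on=["compound", "run"], suffixes=("_par", "_res"))
    rows = []
    for compound, sub in merged.groupby("compound", sort=True):
        fit_ok = bool(sub["converged_par"].all() and sub["converged_res"].all())
        if fit_ok:
            adm = delta_mv(sub["mv_res"].to_numpy(), sub["mv_par"].to_numpy())
            fcs = [ic50_log2fc(r, p) for r, p in
                   zip(sub["abs_ic50_uM_res"], sub["abs_ic50_uM_par"])]
            fcs = [f for f in fcs if f is not None]
            fc = float(np.mean(fcs)) if len(fcs) == len(sub) else np.nan
        else:
            adm, fc = np.nan, np.nan
        rows.append({"compound": compound, "avg_delta_mv": adm,
                     "ic50_log2fc": fc, "fit_ok": fit_ok})
    table = pd.DataFrame(rows)

    if annotations is not None:
        table = table.merge(annotations[["compound", "target_annotation"]],
                            on="compound", how="left")
    else:
        table["target_annotation"] = ""
    table["target_annotation"] = table["target_annotation"].fillna("")
    return table


def call_hits(records: pd.DataFrame,
              delta_mv_threshold: float = DELTA_MV_THRESHOLD,
              fc_threshold: float = IC50_FC_THRESHOLD) -> pd.DataFrame:
    """Flag hits by threshold and rank ascending by Avg Delta MV.

    Both thresholds are boundary-inclusive.  Compounds with undefined
    IC50 fold change (either IC50 not reached) are never FC hits;
    compounds that failed to fit are excluded from both criteria.
    Ties in the ranking are broken by compound identifier.
    """
    if not (np.isfinite(delta_mv_threshold) and np.isfinite(fc_threshold)):
        raise ValueError("thresholds must be finite")
    out = records.copy()
    ok = out["fit_ok"] if "fit_ok" in out.columns else pd.Series(True, index=out.index)
    out["hit_delta_mv"] = ok & (out["avg_delta_mv"] <= delta_mv_threshold)
    out["hit_ic50fc"] = (ok & out["ic50_log2fc"].notna()
                         & (out["ic50_log2fc"] <= fc_threshold))
    out = out.sort_values(["avg_delta_mv", "compound"],
                          kind="mergesort", na_position="last")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def plot_hits(hit_table: pd.DataFrame, path,
              delta_mv_threshold: float = DELTA_MV_THRESHOLD):
    """Bar plot of Delta-MV hits in ascending order, annotated by target."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hits = hit_table[hit_table["hit_delta_mv"]]
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(hits) + 1.5), 4))
    ax.bar(range(len(hits)), hits["avg_delta_mv"], color="#4878d0")
    ax.set_xticks(range(len(hits)))
    ax.set_xticklabels(hits["compound"], rotation=90, fontsize=7)
    for i, t in enumerate(hits["target_annotation"]):
        ax.text(i, 0.005, str(t), rotation=90, ha="center",
                va="bottom", fontsize=6)
    ax.axhline(delta_mv_threshold, ls="--", lw=0.8, color="grey")
    ax.set_ylabel("Avg Delta MV (resistant - parental)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
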