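"""Bliss-independence and highest-single-agent scoring of dose matrices.

A combination experiment titrates drug A against drug B on a dose grid
that includes a zero dose for each drug, so the first row and column
hold the single-agent responses.  Viability fractions are converted to
fractional inhibition (1 - viability, clipped to [0, 1]) and each
combination cell is scored against two null models:

* Bliss independence: expected combined inhibition C = A + B - A*B,
  the probabilistic-independence null; Delta.Bliss = observed - expected
  (positive = synergy).  Delta.Bliss summed over all combination cells
  gives the Bliss sum (0 additive, > 0 synergy, < 0 antagonism).
* HSA (highest single agent): excess of the combination over the better
  single agent at the matching doses, observed - max(A, B).

Because max(a, b) <= a + b - a*b on [0, 1]^2, the HSA score dominates
Delta.Bliss pointwise and the HSA sum dominates the Bliss sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SynergyMatrix",
    "bliss_expectation",
    "delta_bliss",
    "bliss_sum",
    "hsa_score",
    "analyze_matrix",
    "read_matrix_csv",
    "summarize_replicates",
    "plot_heatmaps",
]


def bliss_expectation(a, b):
    """Expected combined inhibition under Bliss independence: a + b - a*b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any((a < 0) | (a > 1) | (b < 0) | (b > 1)):
        raise ValueError("fractional inhibitions must lie in [0, 1]")
    return a + b - a * b


def delta_bliss(observed, expected):
    """Observed minus Bliss-expected inhibition; positive = synergy."""
    return np.asarray(observed, dtype=float) - np.asarray(expected, dtype=float)


def hsa_score(observed, a, b):
    """Excess inhibition of the combination over the highest single agent."""
    return (np.asarray(observed, dtype=float)
            - np.maximum(np.asarray(a, dtype=float), np.asarray(b, dtype=float)))


@dataclass(frozen=True)
class SynergyMatrix:
    """Scored dose-grid combination experiment.

    ``inhibition`` is indexed [i_dose_a, j_dose_b] with the dose-0 row
    and column holding single-agent values; ``delta_bliss`` and ``hsa``
    are defined on combination cells only (NaN on single-agent cells).
    """

    drug_a: str
    drug_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    inhibition: np.ndarray
    delta_bliss: np.ndarray
    hsa: np.ndarray
    bliss_sum: float
    hsa_sum: float

    @property
    def n_combination_cells(self) -> int:
        return (len(self.doses_a) - 1) * (len(self.doses_b) - 1)


def _score_grid(doses_a, doses_b, inhibition):
    single_a = inhibition[:, 0]   # drug A alone, varying dose_a
    single_b = inhibition[0, :]   # drug B alone
    exp = bliss_expectation(single_a[:, None], single_b[None, :])
    db = delta_bliss(inhibition, exp)
    hs = hsa_score(inhibition, single_a[:, None], single_b[None, :])
    db[0, :] = np.nan
    db[:, 0] = np.nan
    hs[0, :] = np.nan
    hs[:, 0] = np.nan
    return db, hs


def analyze_matrix(frame: pd.DataFrame, drug_a: str | None = None,
                   drug_b: str | None = None) -> SynergyMatrix:
    """Score a long-format dose-matrix viability table.

    Parameters
    ----------
    frame : long CSV frame with columns
        ``drug_a, drug_b, dose_a_uM, dose_b_uM, replicate, viability``.
        Dose-0 rows/columns (single agents and the double-vehicle cell)
        are mandatory.  Replicates are averaged per cell before scoring.

    Viability is converted to inhibition as ``1 - viability`` clipped to
    [0, 1]; stimulation above vehicle therefore scores as zero
    inhibition.
    """
    df = frame.copy()
    if drug_a is None:
        drug_a = str(df["drug_a"].iloc[0])
    if drug_b is None:
        drug_b = str(df["drug_b"].iloc[0])

    cell = (df.groupby(["dose_a_uM", "dose_b_uM"])["viability"]
              .mean().reset_index())
    doses_a = np.sort(cell["dose_a_uM"].unique())
    doses_b = np.sort(cell["dose_b_uM"].unique())
    if doses_a[0] != 0 or doses_b[0] != 0:
        raise ValueError("dose grid must include dose 0 for both drugs")
    grid = cell.pivot(index="dose_a_uM", columns="dose_b_uM",
                      values="viability")
    grid = grid.reindex(index=doses_a, columns=doses_b)
    if grid.isna().any().any():
        raise ValueError("ragged dose grid: every (dose_a, dose_b) cell "
                         "must be measured")

    inhibition = np.clip(1.0 - grid.to_numpy(float), 0.0, 1.0)
    db, hs = _score_grid(doses_a, doses_b, inhibition)
    return SynergyMatrix(
        drug_a=drug_a, drug_b=drug_b, doses_a=doses_a, doses_b=doses_b,
        inhibition=inhibition, delta_bliss=db, hsa=hs,
        bliss_sum=float(np.nansum(db)), hsa_sum=float(np.nansum(hs)))


def bliss_sum(matrix: SynergyMatrix) -> float:
    """Sum of Delta.Bliss over all combination cells (both doses > 0)."""
    return matrix.bliss_sum


def read_matrix_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["drug_a", "drug_b", "dose_a_uM", "dose_b_uM",
                "replicate", "viability"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"matrix table missing columns: {missing}")
    return df


def summarize_replicates(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-biological-replicate Bliss/HSA sums with mean +/- SD summary.

    A ``biological_replicate`` column splits independent experiments;
    within each, technical ``replicate`` rows are averaged per cell.
    Returns one row per biological replicate plus a ``mean``/``sd``
    attrs entry on the frame.
    """
    if "biological_replicate" not in frame.columns:
        frame = frame.assign(biological_replicate=1)
    rows = []
    for rep, sub in frame.groupby("biological_replicate"):
        m = analyze_matrix(sub)
        rows.append({"replicate": rep, "bliss_sum": m.bliss_sum,
                     "hsa_sum": m.hsa_sum,
                     "n_cells": m.n_combination_cells})
    out = pd.DataFrame(rows)
    out.attrs["bliss_sum_mean"] = float(out["bliss_sum"].mean())
    out.attrs["bliss_sum_sd"] = float(out["bliss_sum"].std(ddof=1)) \
        if len(out) > 1 else float("nan")
    return out


def matrix_to_frame(m: SynergyMatrix) -> pd.DataFrame:
    """Flatten a scored matrix to a per-cell long table."""
    ia, ib = np.meshgrid(np.arange(len(m.doses_a)),
                         np.arange(len(m.doses_b)), indexing="ij")
    exp = bliss_expectation(m.inhibition[:, 0][:, None],
                            m.inhibition[0, :][None, :])
    return pd.DataFrame({
        "dose_a_uM": m.doses_a[ia.ravel()],
        "dose_b_uM": m.doses_b[ib.ravel()],
        "inhibition": m.inhibition.ravel(),
        "bliss_expected": exp.ravel(),
        "delta_bliss": m.delta_bliss.ravel(),
        "hsa": m.hsa.ravel(),
    })


def plot_heatmaps(m: SynergyMatrix, path):
    """Three-panel heatmap: % inhibition, Delta.Bliss, HSA."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))
    panels = [(100 * m.inhibition, "% viability inhibition", "viridis"),
              (m.delta_bliss, "Delta.Bliss", "coolwarm"),
              (m.hsa, "HSA", "coolwarm")]
    for ax, (grid, title, cmap) in zip(axes, panels):
        im = ax.imshow(grid, origin="lower", aspect="auto", cmap=cmap)
        ax.set_title(title, fontsize=9)
        ax.set_xlabel(f"{m.drug_b} dose index")
        ax.set_ylabel(f"{m.drug_a} dose index")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.suptitle(f"{m.drug_a} x {m.drug_b}  Bliss sum={m.bliss_sum:.2f}  "
                 f"HSA sum={m.hsa_sum:.2f}", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
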