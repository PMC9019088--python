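"""Plate normalization, four-parameter Hill fitting and potency statistics.

Viability plates are normalized to the per-plate median of vehicle
(DMSO) wells, grouped into per-(compound, cell line) titrations, and fit
with the four-parameter Hill model

    v(d) = bottom + (top - bottom) / (1 + (d / ec50)**slope)

optionally by iteratively reweighted least squares with Tukey's biweight
to resist outlier wells.  From a converged fit two summary statistics
are derived: the absolute IC50 (the dose at which fitted viability
crosses 0.5, i.e. 50% inhibition relative to vehicle control) and the
mean fitted viability (MV) across the tested doses, an AUC-like summary
of potency and efficacy combined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseSeries",
    "HillFit",
    "AbsoluteIC50",
    "NormalizationError",
    "normalize_plate",
    "read_plate_csv",
    "fit_hill",
    "hill_curve",
    "absolute_ic50",
    "mean_viability",
    "fit_table",
    "write_fit_table",
]

#: Tukey biweight tuning constant (95% Gaussian efficiency).
TUKEY_C = 4.685
#: |top - bottom| below which the curve is considered flat / unidentifiable.
IDENTIFIABILITY_SPAN = 0.05

PLATE_COLUMNS = [
    "plate_id", "well", "cell_line", "compound",
    "dose_uM", "replicate", "signal", "is_vehicle",
]


class NormalizationError(ValueError):
    """Raised when a plate cannot be normalized to its vehicle wells."""


@dataclass(frozen=True)
class DoseSeries:
    """One compound x cell-line titration with replicate viabilities.

    ``doses`` and ``viability`` are parallel flat arrays: each viability
    point carries its own dose, so replicate counts may differ per dose.
    Viability is fraction-of-control (vehicle median = 1.0).
    """

    compound: str
    cell_line: str
    doses: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        v = np.asarray(self.viability, dtype=float)
        if d.shape != v.shape:
            raise ValueError("doses and viability must be parallel arrays")
        if np.any(d <= 0):
            raise ValueError("doses must be strictly positive")
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "viability", v)

    @property
    def unique_doses(self) -> np.ndarray:
        return np.unique(self.doses)


@dataclass(frozen=True)
class HillFit:
    """Four-parameter Hill fit with robust-fit diagnostics."""

    top: float
    bottom: float
    ec50: float
    slope: float
    robust: bool
    weights: np.ndarray
    rss: float
    converged: bool
    identifiable: bool = True
    n_iter: int = 1

    def predict(self, dose) -> np.ndarray:
        return hill_curve(np.asarray(dose, dtype=float),
                          self.top, self.bottom, self.ec50, self.slope)


@dataclass(frozen=True)
class AbsoluteIC50:
    """Dose of 50% inhibition relative to vehicle, or a not-reached sentinel."""

    value: float | None
    extrapolated: bool = False

    @property
    def reached(self) -> bool:
        return self.value is not None


def hill_curve(dose, top, bottom, ec50, slope):
    """Evaluate the four-parameter Hill curve (decreasing for slope > 0)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ec50) ** slope)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def read_plate_csv(path) -> pd.DataFrame:
    """Read a long-format plate CSV and validate its schema."""
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    _validate_plate_frame(df)
    return df


def _validate_plate_frame(df: pd.DataFrame) -> None:
    if (df["signal"] < 0).any():
        bad = df.index[df["signal"] < 0][0]
        raise ValueError(f"negative signal at row {bad}")
    if (df["dose_uM"] < 0).any():
        bad = df.index[df["dose_uM"] < 0][0]
        raise ValueError(f"negative dose at row {bad}")
    veh = df["is_vehicle"].astype(bool)
    if ((df["dose_uM"] == 0) != veh).any():
        raise ValueError("is_vehicle flag must match dose == 0")
    dup = df.duplicated(subset=["plate_id", "well"])
    if dup.any():
        raise ValueError(f"duplicate (plate_id, well) at row {df.index[dup][0]}")


def normalize_plate(records: pd.DataFrame) -> list[DoseSeries]:
    """Normalize raw signals to per-plate vehicle medians.

    Parameters
    ----------
    records : DataFrame with the plate schema
        (``plate_id, well, cell_line, compound, dose_uM, replicate,
        signal, is_vehicle``).

    Returns
    -------
    list of DoseSeries, one per (compound, cell_line) pair, pooling all
    plates.  Vehicle wells only set the scale; they do not appear in the
    output series.
    """
    df = records.copy()
    _validate_plate_frame(df)
    df["is_vehicle"] = df["is_vehicle"].astype(bool)

    viab = np.empty(len(df), dtype=float)
    for plate, idx in df.groupby("plate_id").groups.items():
        sub = df.loc[idx]
        veh = sub.loc[sub["is_vehicle"], "signal"]
        if len(veh) == 0:
            raise NormalizationError(f"plate {plate!r} has no vehicle wells")
        med = float(veh.median())
        if med == 0:
            raise NormalizationError(
                f"plate {plate!r} is degenerate: vehicle median signal is 0")
        viab[df.index.get_indexer(idx)] = sub["signal"].to_numpy() / med
    df["viability"] = viab

    treated = df[~df["is_vehicle"]]
    out = []
    for (compound, cell_line), sub in treated.groupby(
            ["compound", "cell_line"], sort=True):
        sub = sub.sort_values("dose_uM")
        out.append(DoseSeries(
            compound=str(compound), cell_line=str(cell_line),
            doses=sub["dose_uM"].to_numpy(float),
            viability=sub["viability"].to_numpy(float)))
    return out


# ---------------------------------------------------------------------------
# Hill fitting
# ---------------------------------------------------------------------------

def _initial_params(d: np.ndarray, v: np.ndarray):
    order = np.argsort(d)
    d, v = d[order], v[order]
    lo, hi = d[0], d[-1]
    top0 = float(np.mean(v[d == lo]))
    bottom0 = float(np.mean(v[d == hi]))
    mid = 0.5 * (top0 + bottom0)
    ec50_0 = float(d[np.argmin(np.abs(v - mid))])
    return top0, bottom0, ec50_0, 1.0


def _bounds(d: np.ndarray):
    dmin, dmax = float(np.min(d)), float(np.max(d))
    lo = np.array([0.0, -0.2, math.log10(dmin / 1e3), 1e-3])
    hi = np.array([2.0, 2.0, math.log10(dmax * 1e3), 10.0])
    return lo, hi


def _wls_fit(d, v, w, x0, lo, hi):
    sw = np.sqrt(w)

    def resid(p):
        top, bottom, log_ec50, slope = p
        return sw * (hill_curve(d, top, bottom, 10.0 ** log_ec50, slope) - v)

    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    return sol


def fit_hill(series: DoseSeries, robust: bool = False,
             max_iter: int = 50, tol: float = 1e-8) -> HillFit:
    """Fit the four-parameter Hill model to a titration.

    With ``robust=True`` the ordinary fit is refined by iteratively
    reweighted least squares using Tukey's biweight (tuning constant
    4.685, scale 1.4826 x MAD of residuals re-estimated each iteration),
    which drives the weight of gross outliers to zero.
    """
    d, v = series.doses, series.viability
    if len(series.unique_doses) < 4:
        raise ValueError(
            f"{series.compound}/{series.cell_line}: need >= 4 distinct doses, "
            f"got {len(series.unique_doses)}")
    if not np.all(np.isfinite(v)):
        raise ValueError("viability values must be finite")

    top0, bottom0, ec50_0, slope0 = _initial_params(d, v)
    lo, hi = _bounds(d)
    x0 = np.clip(
        np.array([top0, bottom0, math.log10(ec50_0), slope0]),
        lo + 1e-9, hi - 1e-9)

    w = np.ones_like(v)
    sol = _wls_fit(d, v, w, x0, lo, hi)
    converged = bool(sol.success)
    n_iter = 1

    if robust:
        x_prev = sol.x
        for n_iter in range(2, max_iter + 2):
            top, bottom, log_ec50, slope = x_prev
            r = v - hill_curve(d, top, bottom, 10.0 ** log_ec50, slope)
            scale = 1.4826 * float(np.median(np.abs(r - np.median(r))))
            if scale <= 0:
                # residuals (near-)constant: nothing to down-weight
                w = np.ones_like(v)
                break
            u = r / (TUKEY_C * scale)
            w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
            sol = _wls_fit(d, v, w, x_prev, lo, hi)
            step = np.max(np.abs(sol.x - x_prev) / (np.abs(x_prev) + 1e-12))
            x_prev = sol.x
            if step < tol:
                break
        converged = bool(sol.success)

    top, bottom, log_ec50, slope = sol.x
    if bottom > top:  # slope > 0 is enforced, so this only arises on flat data
        top, bottom = bottom, top
    fit = HillFit(
        top=float(top), bottom=float(bottom), ec50=float(10.0 ** log_ec50),
        slope=float(slope), robust=robust, weights=w,
        rss=float(np.sum(w * (v - hill_curve(d, top, bottom,
                                             10.0 ** log_ec50, slope)) ** 2)),
        converged=converged,
        identifiable=bool(abs(top - bottom) >= IDENTIFIABILITY_SPAN),
        n_iter=n_iter)
    return fit


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def absolute_ic50(fit: HillFit, tested_doses) -> AbsoluteIC50:
    """Dose at which the fitted curve attains viability 0.5.

    Solved in closed form:
    ``d = ec50 * ((top - 0.5) / (0.5 - bottom)) ** (1 / slope)``.
    Returns the not-reached sentinel when the curve never crosses 0.5
    (bottom >= 0.5 or top <= 0.5) or when the fit is unidentifiable;
    ``extrapolated`` flags a crossing outside the tested dose range.
    """
    if not fit.converged:
        raise ValueError("cannot derive IC50 from an unconverged fit")
    if not fit.identifiable:
        return AbsoluteIC50(value=None)
    if fit.bottom >= 0.5 or fit.top <= 0.5:
        return AbsoluteIC50(value=None)
    d = fit.ec50 * ((fit.top - 0.5) / (0.5 - fit.bottom)) ** (1.0 / fit.slope)
    doses = np.asarray(tested_doses, dtype=float)
    extrap = bool(d < doses.min() or d > doses.max())
    return AbsoluteIC50(value=float(d), extrapolated=extrap)


def mean_viability(fit: HillFit, tested_doses) -> float:
    """Mean fitted viability across the tested doses, floored at 0.

    The arithmetic mean of the fitted curve evaluated at the discrete
    tested doses; on a uniform log-dose grid this is the (rectangle-rule)
    area under the viability curve.
    """
    if not fit.converged:
        raise ValueError("cannot derive mean viability from an unconverged fit")
    doses = np.unique(np.asarray(tested_doses, dtype=float))
    mv = float(np.mean(fit.predict(doses)))
    return max(mv, 0.0)


# ---------------------------------------------------------------------------
# Table-level driver
# ---------------------------------------------------------------------------

def fit_table(series_list, robust: bool = False) -> pd.DataFrame:
    """Fit every series and tabulate parameters, IC50 and MV.

    Unconverged fits are retained with ``converged=False`` and NaN
    summary statistics so downstream screening can flag them.
    """
    rows = []
    for s in series_list:
        fit = fit_hill(s, robust=robust)
        if fit.converged:
            ic50 = absolute_ic50(fit, s.unique_doses)
            mv = mean_viability(fit, s.unique_doses)
        else:
            ic50, mv = AbsoluteIC50(value=None), float("nan")
        rows.append({
            "compound": s.compound, "cell_line": s.cell_line,
            "top": fit.top, "bottom": fit.bottom, "ec50_uM": fit.ec50,
            "slope": fit.slope,
            "abs_ic50_uM": ic50.value if ic50.reached else np.nan,
            "ic50_reached": ic50.reached, "mv": mv,
            "converged": fit.converged,
        })
    return pd.DataFrame(rows)


def write_fit_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.6g")
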