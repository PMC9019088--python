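"""Longitudinal xenograft growth modelling and AUC-based growth rates.

Tumor volumes from caliper measurements (V = L*W*W/2) grow roughly
exponentially, so analysis happens on the natural-log scale.  Each
treatment group's ln-volume trajectory is modelled as a penalized cubic
regression spline of study day plus a per-animal random intercept,

    ln V_ij = f_g(t_ij) + b_i + eps_ij,   b_i ~ N(0, s_b^2),

fit in the mixed-model representation of the penalized spline with the
smoothing and intercept variance components estimated by REML.  The
model tolerates moderate dropout (animals euthanized when volume exceeds
2000 mm3 or weight loss exceeds 20%) because each animal contributes
whatever observations it has.

Group efficacy is summarized by an AUC-based growth rate: the fitted
curve's baseline-corrected area over the common study period [0, T],

    rate = (integral_0^T [f(t) - f(0)] dt) / (T^2 / 2),

in natural-log units per day.  The T^2/2 divisor is a slope-equivalence
normalization: for exactly log-linear growth the rate equals the log
slope, and otherwise it is the constant log-linear rate that would have
produced the same baseline-corrected AUC.  The treatment effect is the
growth contrast (eGaIT), rate(treatment) - rate(reference); more
negative means stronger anti-tumor effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize

__all__ = [
    "GrowthFit",
    "GrowthContrast",
    "tumor_volume",
    "prepare_growth_frame",
    "common_period",
    "fit_group_curves",
    "auc_growth_rate",
    "growth_contrast",
    "body_weight_change",
    "plot_growth_curves",
]

SPLINE_DEGREE = 3
DEFAULT_INTERIOR_KNOTS = 4


def tumor_volume(length_mm, width_mm, auto_swap: bool = False):
    """Caliper tumor volume (L x W x W) / 2 in mm3."""
    L = np.asarray(length_mm, dtype=float)
    W = np.asarray(width_mm, dtype=float)
    if np.any(W > L):
        if auto_swap:
            L, W = np.maximum(L, W), np.minimum(L, W)
        else:
            raise ValueError("width exceeds length; pass auto_swap=True to "
                             "reorder caliper dimensions")
    if np.any(W < 0):
        raise ValueError("caliper dimensions must be non-negative")
    out = L * W * W / 2.0
    return float(out) if out.ndim == 0 else out


def prepare_growth_frame(df: pd.DataFrame,
                         auto_swap: bool = False) -> pd.DataFrame:
    """Derive volume_mm3 from calipers when absent; validate the schema."""
    df = df.copy()
    if "volume_mm3" not in df.columns:
        df["volume_mm3"] = tumor_volume(df["length_mm"], df["width_mm"],
                                        auto_swap=auto_swap)
    for col in ("animal_id", "group", "day"):
        if col not in df.columns:
            raise ValueError(f"growth table missing column {col!r}")
    if (df["day"] < 0).any():
        raise ValueError("study days must be non-negative")
    dup = df.duplicated(subset=["animal_id", "day"])
    if dup.any():
        raise ValueError("repeated day within an animal")
    return df


# ---------------------------------------------------------------------------
# Penalized-spline mixed model machinery
# ---------------------------------------------------------------------------

def _knot_vector(days: np.ndarray, n_interior: int) -> np.ndarray:
    """Clamped cubic knot vector with interior knots at day quantiles."""
    lo, hi = float(np.min(days)), float(np.max(days))
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(np.unique(days), qs)
    interior = np.unique(interior[(interior > lo) & (interior < hi)])
    return np.concatenate([
        np.full(SPLINE_DEGREE + 1, lo), interior,
        np.full(SPLINE_DEGREE + 1, hi)])


def _basis_matrix(t: np.ndarray, knots: np.ndarray) -> np.ndarray:
    x = np.clip(np.asarray(t, dtype=float), knots[0], knots[-1])
    return BSpline.design_matrix(x, knots, SPLINE_DEGREE,
                                 extrapolate=False).toarray()


def _penalty_matrix(knots: np.ndarray) -> np.ndarray:
    """Gram matrix of second derivatives, int B_i'' B_j'' dt, exactly.

    Second derivatives of cubics are piecewise linear, so 2-point
    Gauss-Legendre per knot span integrates their products exactly.
    """
    p = len(knots) - SPLINE_DEGREE - 1
    spans = np.unique(knots)
    gauss_x = np.array([-1, 1]) / np.sqrt(3.0)
    P = np.zeros((p, p))
    eye = np.eye(p)
    d2 = [BSpline(knots, eye[i], SPLINE_DEGREE).derivative(2)
          for i in range(p)]
    for a, b in zip(spans[:-1], spans[1:]):
        mid, half = (a + b) / 2.0, (b - a) / 2.0
        pts = mid + half * gauss_x
        vals = np.array([f(pts) for f in d2])           # p x 2
        P += half * vals @ vals.T
    return P


def _basis_integral(knots: np.ndarray, T: float) -> np.ndarray:
    """Vector of int_0^T B_i(t) dt for each basis function."""
    p = len(knots) - SPLINE_DEGREE - 1
    eye = np.eye(p)
    lo = knots[0]
    return np.array([
        BSpline(knots, eye[i], SPLINE_DEGREE).integrate(lo, T)
        for i in range(p)])


def _reml_neg2(logv: np.ndarray, y, Xf, Zs, Za) -> float:
    """-2 REML log-likelihood profile in the two log variance ratios."""
    n, pf = Xf.shape
    V = np.eye(n)
    if Zs.shape[1]:
        V = V + np.exp(logv[0]) * (Zs @ Zs.T)
    if Za.shape[1]:
        V = V + np.exp(logv[1]) * (Za @ Za.T)
    try:
        Lc = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf
    logdetV = 2.0 * np.sum(np.log(np.diag(Lc)))
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, Xf)
    XtViX = Xf.T @ Vi_X
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtViX, Xf.T @ Vi_y)
    r = y - Xf @ beta
    quad = float(r @ np.linalg.solve(V, r))
    quad = max(quad, 1e-300)
    return (n - pf) * np.log(quad / (n - pf)) + logdetV + logdetX


@dataclass(frozen=True)
class GrowthFit:
    """Fitted group-level ln-volume curve with uncertainty.

    ``gamma`` are cubic B-spline coefficients on ``knots``;
    ``cov_gamma`` is their (Bayesian) posterior covariance, from which
    standard errors of any linear functional of the curve — including
    the AUC growth rate — are propagated.
    """

    group: str
    knots: np.ndarray
    gamma: np.ndarray
    cov_gamma: np.ndarray
    animal_effects: pd.Series
    sigma2: float
    n_animals: int
    n_obs: int
    day_max: float

    def predict(self, days) -> np.ndarray:
        """Fitted group-mean ln-volume at the given days."""
        return _basis_matrix(np.asarray(days, dtype=float), self.knots) @ self.gamma

    def predict_se(self, days) -> np.ndarray:
        B = _basis_matrix(np.asarray(days, dtype=float), self.knots)
        return np.sqrt(np.einsum("ij,jk,ik->i", B, self.cov_gamma, B))

    def _rate_functional(self, T: float) -> np.ndarray:
        if T <= 0:
            raise ValueError("study period T must be positive")
        if T > self.day_max + 1e-9:
            raise ValueError(
                f"group {self.group!r}: T={T} exceeds fitted support "
                f"[0, {self.day_max}]")
        ib = _basis_integral(self.knots, T)
        b0 = _basis_matrix(np.array([self.knots[0]]), self.knots)[0]
        return (ib - T * b0) / (T * T / 2.0)

    def rate(self, T: float) -> float:
        return float(self._rate_functional(T) @ self.gamma)

    def rate_se(self, T: float) -> float:
        c = self._rate_functional(T)
        return float(np.sqrt(c @ self.cov_gamma @ c))


@dataclass(frozen=True)
class GrowthContrast:
    """AUC-rate difference between a treatment and a reference group."""

    treatment_group: str
    reference_group: str
    contrast: float
    se: float
    ci95: tuple[float, float]
    T: float


def fit_group_curves(frame: pd.DataFrame,
                     n_interior_knots: int = DEFAULT_INTERIOR_KNOTS,
                     lam_spline: float | None = None,
                     lam_animal: float | None = None,
                     value_col: str = "volume_mm3",
                     log_transform: bool = True) -> dict[str, GrowthFit]:
    """Fit per-group penalized-spline mixed models of ln(volume) vs day.

    Each group is fit independently: ln-volume regressed on a cubic
    B-spline of day (interior knots at observed-day quantiles,
    second-derivative penalty) plus a per-animal random intercept.  The
    smoothing parameter and the intercept variance are variance ratios
    estimated by REML; ``lam_spline`` / ``lam_animal`` fix either to a
    chosen value instead.

    Censored/dropped-out animals contribute their available
    observations; no imputation is performed.
    """
    fits: dict[str, GrowthFit] = {}
    for group, sub in frame.groupby("group", sort=True):
        if sub["animal_id"].nunique() < 2:
            raise ValueError(f"group {group!r}: need >= 2 animals")
        if sub["day"].nunique() < 3:
            raise ValueError(f"group {group!r}: need >= 3 timepoints")
        vals = sub[value_col].to_numpy(float)
        if log_transform:
            if np.any(vals <= 0):
                raise ValueError(f"group {group!r}: non-positive volumes")
            y = np.log(vals)
        else:
            y = vals
        days = sub["day"].to_numpy(float)
        animals = sub["animal_id"].to_numpy()

        n_int = min(n_interior_knots, max(sub["day"].nunique() - 2, 0))
        knots = _knot_vector(days, n_int)
        B = _basis_matrix(days, knots)
        P = _penalty_matrix(knots)

        # mixed representation: null space of the curvature penalty (lines)
        # stays fixed, the penalized directions become random effects
        s, U = np.linalg.eigh(P)
        null = s < max(s.max(), 1.0) * 1e-10
        U0, Up, sp = U[:, null], U[:, ~null], s[~null]
        Xf = B @ U0
        Zs = (B @ Up) / np.sqrt(sp)

        ids, inv = np.unique(animals, return_inverse=True)
        Za = np.zeros((len(y), len(ids)))
        Za[np.arange(len(y)), inv] = 1.0

        if lam_spline is None or lam_animal is None:
            best = None
            for start in ([0.0, 0.0], [4.0, -2.0], [-4.0, 2.0]):
                res = minimize(_reml_neg2, np.array(start),
                               args=(y, Xf, Zs, Za), method="Nelder-Mead",
                               options={"xatol": 1e-4, "fatol": 1e-6,
                                        "maxiter": 400})
                if best is None or res.fun < best.fun:
                    best = res
            vs, va = np.exp(best.x)  # variance ratios sigma_k^2 / sigma^2
        else:
            vs = va = None
        lam_s = (1.0 / max(vs, 1e-12)) if lam_spline is None else lam_spline
        lam_a = (1.0 / max(va, 1e-12)) if lam_animal is None else lam_animal
        lam_s = min(lam_s, 1e10)
        lam_a = min(lam_a, 1e10)

        C = np.hstack([Xf, Zs, Za])
        pf, ps, pa = Xf.shape[1], Zs.shape[1], Za.shape[1]
        Lam = np.diag(np.concatenate([
            np.zeros(pf), np.full(ps, lam_s), np.full(pa, lam_a)]))
        A = C.T @ C + Lam
        theta = np.linalg.solve(A, C.T @ y)
        resid = y - C @ theta
        edf = float(np.trace(np.linalg.solve(A, C.T @ C)))
        sigma2 = float(resid @ resid + lam_s * theta[pf:pf + ps] @
                       theta[pf:pf + ps] + lam_a * theta[pf + ps:] @
                       theta[pf + ps:]) / max(len(y) - edf, 1.0)
        cov_theta = sigma2 * np.linalg.inv(A)

        # back to B-spline coefficient space: gamma = U0 bf + Up sp^-1/2 us
        Tmap = np.hstack([U0, Up / np.sqrt(sp)])
        gamma = Tmap @ theta[:pf + ps]
        cov_gamma = Tmap @ cov_theta[:pf + ps, :pf + ps] @ Tmap.T

        fits[str(group)] = GrowthFit(
            group=str(group), knots=knots, gamma=gamma, cov_gamma=cov_gamma,
            animal_effects=pd.Series(theta[pf + ps:], index=ids),
            sigma2=sigma2, n_animals=len(ids), n_obs=len(y),
            day_max=float(np.max(days)))
    return fits


def common_period(frame: pd.DataFrame, retention: float = 0.5) -> float:
    """Last day at which every group retains >= ``retention`` of animals."""
    days = np.sort(frame["day"].unique())
    T = float(days[0])
    for d in days:
        ok = True
        for _, sub in frame.groupby("group"):
            enrolled = sub["animal_id"].nunique()
            present = sub.loc[sub["day"] >= d, "animal_id"].nunique()
            if present < retention * enrolled:
                ok = False
                break
        if ok:
            T = float(d)
    return T


def auc_growth_rate(fit: GrowthFit, T: float) -> tuple[float, float]:
    """AUC-based growth rate over [0, T] and its standard error.

    rate = (int_0^T [f(t) - f(0)] dt) / (T^2/2), in ln units per day;
    the spline basis is integrated analytically, so for an exactly
    log-linear fitted curve the rate equals its slope to machine
    precision.
    """
    return fit.rate(T), fit.rate_se(T)


def growth_contrast(fit_trt: GrowthFit, fit_ref: GrowthFit,
                    T: float) -> GrowthContrast:
    """Growth contrast (eGaIT): rate(treatment) - rate(reference).

    The two groups are fit independently, so the contrast variance is
    the sum of the two rate variances; the 95% CI uses the normal
    quantile on the delta-method standard error.  Negative contrasts
    indicate anti-tumor effect.
    """
    for f in (fit_trt, fit_ref):
        if T > f.day_max + 1e-9:
            raise ValueError(
                f"study period T={T} not covered by both groups "
                f"({fit_trt.group!r} up to {fit_trt.day_max}, "
                f"{fit_ref.group!r} up to {fit_ref.day_max})")
    r_t, se_t = auc_growth_rate(fit_trt, T)
    r_r, se_r = auc_growth_rate(fit_ref, T)
    contrast = r_t - r_r
    se = float(np.hypot(se_t, se_r))
    half = 1.959963984540054 * se
    return GrowthContrast(
        treatment_group=fit_trt.group, reference_group=fit_ref.group,
        contrast=contrast, se=se, ci95=(contrast - half, contrast + half),
        T=T)


def body_weight_change(frame: pd.DataFrame,
                       weight_col: str = "body_weight_g") -> pd.DataFrame:
    """Per-animal % body-weight change from each animal's starting weight.

    Returns the input rows augmented with ``pct_weight_change`` =
    100 * (w(t) - w(0)) / w(0).  Group-level smooth summaries use
    :func:`fit_group_curves` on the raw weights
    (``log_transform=False``) before normalization.
    """
    out = frame.copy().sort_values(["animal_id", "day"])
    pct = np.empty(len(out))
    for _, idx in out.groupby("animal_id").groups.items():
        sub = out.loc[idx]
        w0 = float(sub.iloc[0][weight_col])
        if not np.isfinite(w0) or w0 <= 0:
            raise ValueError(
                f"animal {sub.iloc[0]['animal_id']!r}: missing or "
                "non-positive baseline weight")
        pct[out.index.get_indexer(idx)] = \
            100.0 * (sub[weight_col].to_numpy(float) - w0) / w0
    out["pct_weight_change"] = pct
    return out


def plot_growth_curves(fits: dict[str, GrowthFit], T: float, path):
    """Fitted group ln-volume curves (back-transformed) with 95% bands."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for group, fit in fits.items():
        t = np.linspace(0, min(T, fit.day_max), 100)
        mu = fit.predict(t)
        se = fit.predict_se(t)
        line, = ax.plot(t, np.exp(mu), label=group)
        ax.fill_between(t, np.exp(mu - 1.96 * se), np.exp(mu + 1.96 * se),
                        alpha=0.2, color=line.get_color())
    ax.set_xlabel("study day")
    ax.set_ylabel("fitted tumor volume (mm$^3$)")
    ax.set_yscale("log")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
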