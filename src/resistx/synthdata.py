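"""Seeded synthetic datasets with known truth for every pipeline stage.

Emulates the study's experimental designs so that each analysis module
can be exercised end-to-end against ground truth:

* plate viability assays: 9-point dose titrations in quadruplicate,
  normalized to 42 vehicle wells per plate, multiplicative lognormal
  signal noise;
* paired parental/resistant compound screens (426 compounds by default)
  with a chosen number of implanted differentially sensitive compounds
  whose resistant-line viability is shifted down by a known Delta MV;
* dose-matrix combination experiments generated under Bliss-additive
  (multiplicative survival), synergistic (injected excess inhibition on
  a cell block) or antagonistic truth;
* per-animal exponential tumor growth with lognormal noise, animal
  random intercepts, and euthanasia dropout above 2000 mm3.

Every generator is deterministic given (seed, config) and returns a
machine-readable truth table alongside the simulated measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doseresp import hill_curve

__all__ = [
    "SimulationConfig",
    "default_doses",
    "simulate_dose_response",
    "simulate_screen",
    "simulate_synergy_matrix",
    "simulate_xenograft",
]

#: euthanasia threshold on tumor volume, mm3
CENSOR_VOLUME_MM3 = 2000.0
#: measurement schedule: twice weekly over a 21-day dosing period
DEFAULT_XENO_DAYS = (0, 3, 7, 10, 14, 17, 21)


def default_doses(top_dose: float = 10.0, n: int = 9,
                  fold: float = 3.0) -> np.ndarray:
    """9-point serial dilution (3-fold) from the top dose, ascending, uM."""
    return top_dose / fold ** np.arange(n)[::-1]


@dataclass
class SimulationConfig:
    """Study-design parameters for all generators.

    Defaults mirror the study designs: 9-point 3-fold titrations in
    quadruplicate, a 426-compound screen with 5 implanted hits shifted
    by Delta MV -0.25, 5% signal noise (CV), two biological screen
    runs, and xenograft arms of 9 animals measured twice weekly for 21
    days starting from 300 mm3 tumors.
    """

    seed: int = 0
    n_compounds: int = 426
    n_hits: int = 5
    hit_effect: float = -0.25
    noise_cv: float = 0.05
    doses: np.ndarray = field(default_factory=default_doses)
    n_replicates: int = 4
    n_runs: int = 2
    n_vehicle_wells: int = 42
    vehicle_level: float = 1e5
    # synergy design
    matrix_model: str = "independent"   # independent | excess | antagonistic
    matrix_delta: float = 0.1
    matrix_excess_cells: int = 9
    matrix_noise_cv: float = 0.02
    # xenograft design
    xeno_groups: dict = field(default_factory=lambda: {
        "Vehicle": 0.05, "Treatment": 0.01})
    xeno_n_animals: int = 9
    xeno_days: tuple = DEFAULT_XENO_DAYS
    xeno_v0_mm3: float = 300.0
    xeno_intercept_sd: float = 0.2
    xeno_residual_sd: float = 0.15
    censor_volume: float = CENSOR_VOLUME_MM3

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_hits > self.n_compounds:
            raise ValueError("n_hits cannot exceed n_compounds")
        self.doses = np.asarray(self.doses, dtype=float)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        if "doses" in d:
            d = dict(d, doses=np.asarray(d["doses"], dtype=float))
        return cls(**d)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# Plate-level dose-response simulation
# ---------------------------------------------------------------------------

def simulate_dose_response(config: SimulationConfig, hill_params: dict,
                           cell_line: str = "LINE",
                           rng: np.random.Generator | None = None,
                           plate_prefix: str = "P") -> pd.DataFrame:
    """Simulate raw plates for a set of compounds on one cell line.

    Parameters
    ----------
    hill_params : mapping compound -> (top, bottom, ec50_uM, slope)
        True viability curves; raw signal = vehicle_level * v(d) * noise.

    Compounds are packed onto 384-well plates (each compound occupies
    doses x replicates wells) and every plate carries its own block of
    vehicle wells.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    doses = config.doses
    wells_per_compound = len(doses) * config.n_replicates
    per_plate = max((384 - config.n_vehicle_wells) // wells_per_compound, 1)

    compounds = list(hill_params)
    rows = []
    for chunk_i in range(0, len(compounds), per_plate):
        chunk = compounds[chunk_i:chunk_i + per_plate]
        plate = f"{plate_prefix}{chunk_i // per_plate + 1:03d}"
        well = 0
        veh = config.vehicle_level * _lognormal_factor(
            rng, config.noise_cv, config.n_vehicle_wells)
        for s in veh:
            rows.append((plate, f"W{well:03d}", cell_line, "vehicle",
                         0.0, 1, float(s), True))
            well += 1
        for comp in chunk:
            top, bottom, ec50, slope = hill_params[comp]
            v = hill_curve(doses, top, bottom, ec50, slope)
            noise = _lognormal_factor(
                rng, config.noise_cv, (len(doses), config.n_replicates))
            sig = config.vehicle_level * v[:, None] * noise
            for i, d in enumerate(doses):
                for r in range(config.n_replicates):
                    rows.append((plate, f"W{well:03d}", cell_line, comp,
                                 float(d), r + 1, float(max(sig[i, r], 0.0)),
                                 False))
                    well += 1
    return pd.DataFrame(rows, columns=[
        "plate_id", "well", "cell_line", "compound", "dose_uM",
        "replicate", "signal", "is_vehicle"])


# ---------------------------------------------------------------------------
# Paired screen simulation
# ---------------------------------------------------------------------------

def _screen_params(config: SimulationConfig, rng: np.random.Generator):
    """Draw per-compound true curves and implant differential hits.

    Neutral compounds share identical parameters across the two lines.
    Implanted hits have the resistant-line viability curve shifted down
    by |hit_effect| at every dose, which shifts the fitted MV by exactly
    hit_effect while preserving the Hill shape.
    """
    n = config.n_compounds
    doses = config.doses
    names = [f"CPD{i + 1:04d}" for i in range(n)]
    log_lo, log_hi = np.log10(doses[0]), np.log10(doses[-1])
    ec50 = 10.0 ** rng.uniform(log_lo, log_hi, size=n)
    slope = rng.uniform(0.8, 2.0, size=n)
    bottom = rng.uniform(0.0, 0.5, size=n)
    top = np.ones(n)

    hit_idx = rng.choice(n, size=config.n_hits, replace=False)
    # keep shifted curves non-negative: hits need bottom >= |effect|
    bottom[hit_idx] = rng.uniform(abs(config.hit_effect), 0.5,
                                  size=config.n_hits)
    par, res = {}, {}
    truth = []
    shift = config.hit_effect  # negative = resistant more sensitive
    for i, name in enumerate(names):
        par[name] = (top[i], bottom[i], ec50[i], slope[i])
        if i in hit_idx:
            res[name] = (top[i] + shift, bottom[i] + shift, ec50[i], slope[i])
            truth.append((name, True, shift))
        else:
            res[name] = par[name]
            truth.append((name, False, 0.0))
    truth = pd.DataFrame(truth,
                         columns=["compound", "is_hit", "true_delta_mv"])
    return par, res, truth


def simulate_screen(config: SimulationConfig):
    """Paired parental/resistant screen plates plus the truth table.

    Returns
    -------
    plates : DataFrame of raw plate records for both lines and all
        biological-replicate runs (columns as the plate schema plus
        ``run``).
    truth : per-compound DataFrame ``compound, is_hit, true_delta_mv``.
    """
    rng = np.random.default_rng(config.seed)
    par_params, res_params, truth = _screen_params(config, rng)
    frames = []
    for run in range(1, config.n_runs + 1):
        for line, params in (("parental", par_params),
                             ("resistant", res_params)):
            df = simulate_dose_response(
                config, params, cell_line=line, rng=rng,
                plate_prefix=f"{line[:3].upper()}{run}_")
            df["run"] = run
            frames.append(df)
    return pd.concat(frames, ignore_index=True), truth


# ---------------------------------------------------------------------------
# Synergy-matrix simulation
# ---------------------------------------------------------------------------

def simulate_synergy_matrix(config: SimulationConfig,
                            doses_a: np.ndarray | None = None,
                            doses_b: np.ndarray | None = None,
                            single_a=(1.0, 0.0, 1.0, 1.0),
                            single_b=(1.0, 0.0, 1.0, 1.0),
                            n_replicates: int = 4):
    """Dose-matrix viability table generated under a known truth model.

    Single agents follow Hill curves; the combination viability is
    multiplicative survival v_a * v_b (exact Bliss additivity) with,
    depending on ``config.matrix_model``:

    * ``independent``: no modification (true Bliss sum = 0),
    * ``excess``: viability lowered by ``matrix_delta`` on the
      ``matrix_excess_cells`` highest-dose combination cells (true Bliss
      sum = delta * n_cells),
    * ``antagonistic``: viability raised by the same amount (negative
      truth).

    Returns (long-format frame, truth dict with ``true_bliss_sum``).
    """
    rng = np.random.default_rng(config.seed)
    if doses_a is None:
        doses_a = np.concatenate([[0.0], default_doses(n=5)])
    if doses_b is None:
        doses_b = np.concatenate([[0.0], default_doses(n=5)])
    doses_a = np.sort(np.asarray(doses_a, dtype=float))
    doses_b = np.sort(np.asarray(doses_b, dtype=float))

    va = np.where(doses_a > 0, hill_curve(np.maximum(doses_a, 1e-300),
                                          *single_a), 1.0)
    vb = np.where(doses_b > 0, hill_curve(np.maximum(doses_b, 1e-300),
                                          *single_b), 1.0)
    v = va[:, None] * vb[None, :]

    # modified combination-cell block: lowest positive dose pairs, where
    # combination viability is highest, so the injected shift is not
    # truncated by the [0, 1] viability range under the default design
    n_comb_a, n_comb_b = len(doses_a) - 1, len(doses_b) - 1
    k = int(np.sqrt(config.matrix_excess_cells))
    if k * k != config.matrix_excess_cells or k > min(n_comb_a, n_comb_b):
        raise ValueError("matrix_excess_cells must be a square number "
                         "fitting the combination grid")
    mask = np.zeros_like(v, dtype=bool)
    mask[1:k + 1, 1:k + 1] = True

    delta = config.matrix_delta
    if config.matrix_model == "excess":
        # realized excess per cell is v - max(v - delta, 0): exact truth
        # even when a cell would clip at zero viability
        v_true = np.where(mask, np.clip(v - delta, 0.0, None), v)
        true_sum = float(np.sum(np.where(mask, v - v_true, 0.0)))
    elif config.matrix_model == "antagonistic":
        # viability cannot exceed vehicle, so the realized (negative)
        # excess on each cell is v - min(v + delta, 1)
        v_true = np.where(mask, np.clip(v + delta, None, 1.0), v)
        true_sum = float(np.sum(np.where(mask, v - v_true, 0.0)))
    elif config.matrix_model == "independent":
        v_true, true_sum = v, 0.0
    else:
        raise ValueError(f"unknown matrix model {config.matrix_model!r}")

    rows = []
    for rep in range(1, n_replicates + 1):
        noise = _lognormal_factor(rng, config.matrix_noise_cv, v.shape)
        vv = v_true * noise
        vv[0, 0] = 1.0  # double-vehicle cell defines the control scale
        for i, da in enumerate(doses_a):
            for j, db in enumerate(doses_b):
                rows.append(("drugA", "drugB", float(da), float(db),
                             rep, float(vv[i, j])))
    frame = pd.DataFrame(rows, columns=[
        "drug_a", "drug_b", "dose_a_uM", "dose_b_uM", "replicate",
        "viability"])
    return frame, {"true_bliss_sum": true_sum, "model": config.matrix_model}


# ---------------------------------------------------------------------------
# Xenograft simulation
# ---------------------------------------------------------------------------

def simulate_xenograft(config: SimulationConfig):
    """Longitudinal tumor volumes with dropout, plus the truth table.

    Per animal i in group g:
    ``ln V_i(t) = ln V0 + b_i + k_g * t + eps``, with b_i the animal
    intercept (SD ``xeno_intercept_sd``) and eps residual noise (SD
    ``xeno_residual_sd``).  Observations strictly after the first
    crossing of ``censor_volume`` are removed and the animal flagged
    censored (euthanasia rule).  Body weights start near 25 g with a
    small random-walk drift.
    """
    rng = np.random.default_rng(config.seed)
    days = np.asarray(config.xeno_days, dtype=float)
    rows = []
    truth = []
    for group, rate in config.xeno_groups.items():
        for a in range(config.xeno_n_animals):
            animal = f"{group}-{a + 1:02d}"
            b_i = rng.normal(0.0, config.xeno_intercept_sd)
            eps = rng.normal(0.0, config.xeno_residual_sd, size=len(days))
            lnv = np.log(config.xeno_v0_mm3) + b_i + rate * days + eps
            vol = np.exp(lnv)
            w0 = rng.normal(25.0, 1.5)
            dw = np.concatenate([[0.0], np.cumsum(
                rng.normal(0.0, 0.25, size=len(days) - 1))])
            weight = w0 + dw
            over = np.nonzero(vol > config.censor_volume)[0]
            last = over[0] if len(over) else len(days) - 1
            censored = bool(len(over)) and last < len(days) - 1
            for j in range(last + 1):
                rows.append((animal, group, float(days[j]),
                             float(vol[j]), float(weight[j]), censored))
            truth.append((group, animal, rate, b_i, censored))
    data = pd.DataFrame(rows, columns=[
        "animal_id", "group", "day", "volume_mm3", "body_weight_g",
        "censored"])
    truth = pd.DataFrame(truth, columns=[
        "group", "animal_id", "true_rate", "animal_intercept", "censored"])
    return data, truth
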