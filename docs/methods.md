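# Methods

This note documents the models, estimators, numerical choices and
limitations behind each analysis stage, and what the synthetic-data
generators do and do not emulate.

## Plate normalization and the Hill model

Viability is defined as raw signal divided by the median signal of the
vehicle wells on the same plate, so the vehicle median maps to exactly
1.0 by construction and plate-to-plate gain differences cancel. A plate
without vehicle wells, or with a zero vehicle median, is an error — no
fallback scale is invented.

Each (compound, cell line) titration is fit with the four-parameter
Hill curve v(d) = bottom + (top − bottom)/(1 + (d/EC50)^s), a strictly
monotone non-increasing function of dose for s > 0. Fitting minimizes
least squares over all replicate points (replicates are not
pre-averaged; each well keeps its own leverage) with `scipy`'s
trust-region-reflective solver, EC50 parameterized on the log10 scale.

Choices the data do not pin down, fixed as follows:

- **Bounds**: top ∈ [0, 2], bottom ∈ [−0.2, 2], EC50 within
  [min dose/10³, max dose·10³], slope ∈ (0, 10]. Viability above 1
  (stimulation) is retained, not clipped; only the synergy module clips,
  because its scores are defined on fractional inhibitions.
- **Initialization**: top from the mean viability at the lowest dose,
  bottom from the highest dose, EC50 from the dose nearest the
  mid-viability, slope 1.
- **Identifiability**: a fit with |top − bottom| < 0.05 is flagged
  unidentifiable (flat curve; EC50 meaningless) and its IC50 reported
  as not reached.
- **Robust fitting**: iteratively reweighted least squares with Tukey's
  biweight, tuning constant 4.685 (95% Gaussian efficiency), scale
  1.4826·MAD of residuals re-estimated each iteration, at most 50
  iterations, convergence at relative parameter change < 1e-8. When the
  MAD is zero (residuals essentially constant) weights revert to 1 —
  there is nothing to down-weight. With all weights forced to 1 the
  robust path reproduces the ordinary fit.

**Absolute IC50** is solved in closed form,
d = EC50·((top − 0.5)/(0.5 − bottom))^(1/s), defined only when the
curve actually crosses 0.5 (top > 0.5 > bottom); a crossing outside the
tested dose range is flagged extrapolated rather than suppressed.
**Mean viability** is the arithmetic mean of the fitted curve at the
discrete tested doses, floored at 0. On a uniform log-dose grid this
discrete mean differs from a trapezoid AUC only in endpoint weights;
the discrete mean is used because it is invariant to the dose grid's
parameterization and matches the screen's definition of MV.

## Differential screen

Avg Delta MV averages per-run differences (resistant − parental), which
makes the statistic antisymmetric under swapping the two lines. IC50
fold changes are averaged on the log2 scale across runs for the same
symmetry reason. A compound whose curve reaches less than 50% maximum
inhibition in either line has no defined fold change and is excluded
from FC-based calling (it can still be a Delta-MV hit). Compounds that
fail to converge in either line are excluded from both criteria and
flagged. Both thresholds (−0.10 for Avg Delta MV, −1 for log2 FC) are
boundary-inclusive; ranking ties break lexicographically by compound
identifier so output order is deterministic.

## Synergy scoring

Inhibition is 1 − viability clipped to [0, 1] before scoring;
stimulation above vehicle would otherwise make the Bliss product
ill-behaved. Technical replicates are averaged per cell within a
biological replicate; a Bliss sum is computed per biological replicate
and reported as mean ± SD across replicates. The sums run over
combination cells only (both doses > 0) — on single-agent cells
Delta.Bliss is identically zero, so exclusion changes nothing but makes
the cell count explicit; the cell count is exposed for users who want a
per-cell normalized score, while the headline statistic remains the raw
sum. For inhibitions in [0, 1], max(a, b) ≤ a + b − a·b, so the HSA
score dominates Delta.Bliss pointwise and the HSA sum dominates the
Bliss sum; this inequality is enforced as a property test.

## Growth modelling

Volumes are computed from calipers as L·W·W/2 (mm³) and analyzed as
ln V. Each group is fit independently with

ln V_ij = f_g(t_ij) + b_i + ε_ij,  b_i ~ N(0, σ_b²), ε ~ N(0, σ²),

where f_g is a cubic B-spline (interior knots at observed-day
quantiles, default 4, reduced automatically when there are few distinct
days) with a second-derivative curvature penalty whose Gram matrix is
integrated exactly (2-point Gauss–Legendre per knot span, exact for the
piecewise-quadratic integrand). The spline is re-expressed in its
mixed-model form — the penalty's null space (straight lines) stays
fixed, the penalized directions become random effects — and the two
variance ratios (smoothing and animal intercept) are estimated jointly
by REML (Nelder–Mead on the 2-d profile criterion from three starts).
REML is used rather than a separate GCV step for the smoother because
the animal intercepts and the smoothing parameter must be estimated
jointly; a fixed-λ override is available for both components.
Coefficient uncertainty uses the Bayesian posterior covariance
σ̂²(CᵀC + Λ)⁻¹ standard for penalized smoothers.

The AUC-based growth rate is the linear functional
rate = (∫₀ᵀ f(t) dt − T·f(0)) / (T²/2) of the spline coefficients, with
the basis integral computed analytically — so for an exactly log-linear
fitted curve the rate equals the slope to machine precision (the
slope-equivalence identity), and for curved growth it is the constant
log-linear rate that would have produced the observed baseline-corrected
AUC. Baseline correction makes rates invariant to rescaling all volumes
by a constant. The growth contrast is the rate difference between two
independently fitted groups; its variance is the sum of the two rate
variances and the 95% CI uses the normal quantile on the delta-method
standard error. The common study period defaults to the last day on
which every group retains at least half of its enrolled animals.
Dropout is handled by simply using each animal's available
observations; no imputation. Body weights are summarized per animal as
100·(w(t) − w(0))/w(0), with group smooths fit on raw weights (no log
transform) by the same spline machinery.

Known limitations: random slopes (animal-specific growth rates) are not
modelled — with ~7 timepoints per animal and 9 animals per arm the
random-intercept model is the most that is reliably estimable; groups
are fit independently, so no variance pooling across arms; the CI does
not propagate uncertainty in the variance components themselves.

## Synthetic-data generators

All generators are deterministic given (seed, config) and emit truth
tables. Defaults mirror the experimental designs they emulate:

- **Plates**: 9-point, 3-fold titrations (top dose 10 μM) in
  quadruplicate, 42 vehicle wells per 384-well plate, multiplicative
  lognormal signal noise with CV 5% (luminescence assays are scale-noise
  dominated), unit-mean so no bias is introduced.
- **Screen**: 426 compounds, 5 implanted hits, two biological-replicate
  runs. Neutral compounds share identical true curves across lines;
  hits have the resistant-line viability curve shifted down by 0.25 at
  every dose, which shifts true MV by exactly −0.25 while preserving
  the Hill shape (hit bottoms are drawn ≥ 0.25 so the shifted curve
  stays non-negative).
- **Synergy matrices**: single agents follow Hill curves; combination
  viability is multiplicative survival v_a·v_b, which is exactly
  Bliss-additive — the generator's null is the scorer's null by
  construction, giving a machine-precision identity test. Synergy
  injects a fixed viability deficit on the lowest-positive-dose 3×3
  combination block, where viability is highest, so the injected excess
  is not truncated by the [0, 1] range; the truth table records the
  realized (post-clipping) excess in any case. Matrix noise defaults to
  CV 2% in quadruplicate.
- **Xenografts**: ln V(t) = ln 300 + b_i + k_g·t + ε with intercept SD
  0.2, residual SD 0.15, arms of 9 animals measured twice weekly for 21
  days (days 0, 3, 7, 10, 14, 17, 21); observations after the first
  crossing of 2000 mm³ are removed and the animal flagged censored,
  emulating the euthanasia rule. The 300 mm³ start sits inside the
  study's 230–350 mm³ enrollment window. Body weights start near 25 g
  with a small random walk.

What the generators do **not** emulate: plate spatial artifacts and
edge effects, pharmacokinetic exposure, assay drift between runs,
heavy-tailed measurement error, correlated noise across doses, animal
body-weight-triggered dropout, and non-exponential (e.g. Gompertz)
tumor growth. Passing tests therefore demonstrate correctness of the
estimators under their stated models and robustness to the injected
perturbations (outlier wells, dropout), not performance on all real
data pathologies.

## Problem sizes in tests and reproduction script

Module tests use reduced designs (e.g. 60-compound screens, 30-seed
recovery loops) to keep the suite fast; the reproduction script and the
acceptance tests run the full-scale designs: the 426-compound screen,
100 Hill-recovery replicates, 200 replicate xenograft studies for CI
coverage, and 10⁶ random triples for the score inequality.
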