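"""Fit xenograft growth curves and compute AUC-based growth contrasts.

Simulates a vehicle arm (0.05 ln/day) and a treated arm (0.01 ln/day),
9 animals each measured twice weekly for 21 days with animal-level
intercept variation and residual noise, fits per-group penalized-spline
mixed models of ln(volume), and reports slope-equivalent growth rates
and the treatment-vs-vehicle growth contrast (eGaIT) with its 95% CI.
"""

import resistx as rx

cfg = rx.SimulationConfig(seed=11)  # Vehicle 0.05, Treatment 0.01 ln/day
data, truth = rx.simulate_xenograft(cfg)

fits = rx.fit_group_curves(data)
T = rx.common_period(data)
print(f"common study period T = {T:.0f} days")
for group, fit in fits.items():
    rate, se = rx.auc_growth_rate(fit, T)
    print(f"{group:>10}: rate = {rate:+.4f} +/- {se:.4f} ln/day "
          f"({fit.n_animals} animals, {fit.n_obs} observations)")

c = rx.growth_contrast(fits["Treatment"], fits["Vehicle"], T)
print(f"\ngrowth contrast (eGaIT) = {c.contrast:+.4f} ln/day, "
      f"95% CI [{c.ci95[0]:+.4f}, {c.ci95[1]:+.4f}]")
print()
print("The rate is the baseline-corrected AUC of the fitted ln-volume curve")
print("divided by T^2/2, i.e. the log-linear slope that would produce the")
print("same AUC; the more negative the contrast, the stronger the")
print("anti-tumor effect (true value here is -0.04).")
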