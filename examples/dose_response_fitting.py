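"""Fit a four-parameter Hill curve to a simulated viability titration.

Simulates one compound measured as a 9-point, 3-fold titration in
quadruplicate with 5% multiplicative signal noise, normalizes the raw
luminescence to the plate's vehicle wells, fits the Hill model both
ordinarily and robustly, and derives the absolute IC50 and mean
viability (MV).
"""

import resistx as rx

cfg = rx.SimulationConfig(seed=1)
true_params = {"drugX": (1.0, 0.05, 0.8, 1.2)}  # top, bottom, ec50 uM, slope
plates = rx.simulate_dose_response(cfg, true_params)

series = rx.normalize_plate(plates)[0]
fit = rx.fit_hill(series, robust=True)
ic50 = rx.absolute_ic50(fit, series.unique_doses)
mv = rx.mean_viability(fit, series.unique_doses)

print(f"true curve:   top=1.00 bottom=0.05 ec50=0.80 uM slope=1.20")
print(f"fitted curve: top={fit.top:.2f} bottom={fit.bottom:.2f} "
      f"ec50={fit.ec50:.2f} uM slope={fit.slope:.2f}")
print(f"absolute IC50 = {ic50.value:.3f} uM (extrapolated={ic50.extrapolated})")
print(f"mean viability (MV) = {mv:.3f}")
print()
print("The absolute IC50 is where the fitted curve crosses 50% of vehicle-")
print("control viability; MV averages the fitted curve over the nine doses,")
print("summarizing potency and efficacy in one AUC-like number in [0, 1].")
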