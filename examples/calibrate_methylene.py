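"""Calibrate the parsimonious methylene-interval model and cross-validate it.

The workflow of a final calibration: simulate (or load) spectra, reference
each one to the glucose anchor at 5.23 ppm, crop to the methylene band
1.05–1.4 ppm, and report full leave-one-out metrics of a 3-component PLS
model plus where its regression coefficients peak.
"""

import numpy as np

from chylopls import (
    METHYLENE_REGION,
    SimulationConfig,
    crop,
    fit_pls,
    loocv_pls,
    reference_dataset,
    regression_coefficient_profile,
    simulate_dataset,
)

ds = reference_dataset(simulate_dataset(153, SimulationConfig(seed=1)))
sub = crop(ds, *METHYLENE_REGION)

cv = loocv_pls(sub, n_components=3)
print(f"methylene interval {METHYLENE_REGION} ppm, {cv.n_components} PLS components, "
      f"n = {cv.n_samples}")
print(f"  RMSECV = {cv.rmsecv:.3f} mmol/L")
print(f"  r² (Pearson, CV predictions vs measured) = {cv.r2:.3f}")
print(f"  predicted-vs-measured line: y = {cv.slope:.4f}x + {cv.intercept:.4f} mmol/L "
      "(ideal: y = x)")

model = fit_pls(sub.X, sub.y, 3, ppm=sub.ppm)
ppm, b = regression_coefficient_profile(model)
peak_b = ppm[np.argmax(np.abs(b))]
print(f"  largest |regression coefficient| at {peak_b:.3f} ppm — the left flank of "
      "the 1.28 ppm methylene peak, where the TG-dependent shift moves intensity")
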