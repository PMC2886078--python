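# Methods

## The calibration problem

The quantity of interest is the triglyceride (TG) concentration carried by
chylomicrons in human plasma, in mmol/L, as measured by the reference
ultracentrifugation + colorimetric assay (UC-TG). The measurement is a 1-D
¹H-NMR spectrum of plasma; the calibration is a linear model y = Xb fitted
by partial least squares (PLS1) on mean-centered data. Chylomicron TG is
not encoded in any single spectral variable: lipoprotein classes produce
nearly identical lipid resonances whose positions are weakly shifted by
particle density and diffusion, so the informative signature is the
position/shape of the methylene band near 1.28 ppm rather than its height.
That is what makes a multivariate model necessary and a single-peak
integration insufficient.

## PLS1 (NIPALS, X-deflation only)

For each latent variable a = 1..A on centered data (Xc, yc):

    w_a = X′y / ‖X′y‖,   t_a = X w_a,   p_a = X′t_a / t_a′t_a,
    q_a = y′t_a / t_a′t_a,   X ← X − t_a p_a′

with b = W(P′W)⁻¹q and the intercept restoring the original scale.
Properties relied on elsewhere (and asserted in the tests): w₁ ∝ Xc′yc
exactly — the covariance interpretation of the first factor; scores are
mutually orthogonal; at A = rank(Xc) the solution coincides with least
squares. y-deflation is omitted because deflated X is orthogonal to all
previous scores, making it mathematically irrelevant for PLS1.

Numerical conventions: weight vectors are unit-norm with the sign fixed so
their largest-magnitude element is positive (bit-reproducible across
platforms); if X deflates below 1e-12 of its original Frobenius norm,
extraction stops early with a warning rather than dividing by a vanishing
score norm. The default A = 3 matches the parsimony regime of single-analyte
NMR calibration; every entry point accepts another value.

## Validation

All reported models use full leave-one-sample-out cross-validation; each
fold refits everything y-dependent, including the centering means, so the
held-out sample never leaks into the training statistics. Referencing and
cropping act per-sample and y-independently, so they are applied once
globally. Headline metrics:

- RMSECV = √(mean((y − ŷ_CV)²)), in mmol/L;
- r² = squared Pearson correlation between cross-validated predictions and
  measured values (the convention under which a reported R and R² form a
  consistent pair); the 1 − SSE/SST variant is reported alongside as
  `r2_residual`;
- the least-squares line of predicted on measured, compared to y = x.

## Interval PLS

The analyzed region's columns are tiled into k near-equal intervals
(defaults: k = 20 over 0.0–5.8 ppm); when p is not divisible by k the first
p mod k intervals (counted from the high-ppm end) get one extra column, so
the tiling is reproducible exactly. Each interval's local model is
cross-validated identically to the global model; the winner is the minimum
RMSECV, ties broken by fewer components, then lower interval index. A local
model that cannot be fitted (too few variables for the requested
components) is recorded as failed and skipped, not fatal. Combining several
winning intervals (synergy iPLS) is deliberately out of scope: the final
model here is a single interval.

## Chemical-shift referencing

Each spectrum is anchored on the α-D-glucose anomeric proton doublet at
5.23 ppm: the maximum intensity in a ±0.10 ppm window locates the peak, and
the anchor position is then refined to sub-grid precision as the
intensity-weighted centroid of the contiguous run of points above half the
peak maximum. The refinement matters: a bare one-point argmax is quantized
to the grid and wanders with single-point noise on a broad-topped doublet
(measured ≈ 3 mppm r.m.s. under the default simulation), which would make
referencing the dominant error source of the entire calibration; the
half-height centroid localizes the anchor to ≈ 0.5 mppm. The axis is
translated and the spectrum linearly resampled back onto the shared grid
(edge points take the edge intensity; the affected extremes are baseline).
A window that lies outside the spectrum, or contains no maximum above the
spectrum's median intensity, raises a referencing error so the sample is
flagged rather than silently mis-aligned.

Only mean centering is applied before regression — no variance scaling or
normalization — because the covariance interpretation of the first PLS
factor presumes centering only. Baseline/phase correction and apodization
are assumed done upstream by the spectrometer software.

## The synthetic data generator

The generator emulates the structure of plasma spectra well enough to
exercise every pipeline stage against known ground truth. Each spectrum is
a sum of Lorentzian resonances L(x) = Aγ²/((x−c)² + γ²) on a shared
descending grid (default 0.0–5.8 ppm, 2901 points = 0.002 ppm step — a
binned-resolution representation of a 500 MHz spectrum):

| resonance            | center (ppm) | γ (ppm) | amplitude (a.u.)            | shift / TG |
|----------------------|--------------|---------|------------------------------|------------|
| lipid methyl         | 0.87         | 0.022   | 0.22 + 0.55·(TG + bg)        | 0.004      |
| lipid methylene      | 1.28         | 0.032   | 0.40 + 1.00·(TG + bg)        | 0.010      |
| ester-vicinal CH₂    | 2.24         | 0.025   | 0.07 + 0.18·(TG + bg)        | 0.010      |
| glucose anomeric (d) | 5.23 ± 0.004 | 0.008   | 1.0 (constant)               | 0          |
| olefinic             | 5.30         | 0.040   | 0.025 + 0.06·(TG + bg)       | 0          |

TG is the chylomicron TG (uniform on 0.08–2.76 mmol/L, the calibration
range); bg is an independent background lipid level (a VLDL/LDL stand-in,
uniform on 0.3–1.2) representing the fact that ultracentrifugation cannot
perfectly separate chylomicrons from density-adjacent lipoproteins and
that non-chylomicron lipid dominates amplitude variation. Because bg is
drawn independently, peak **amplitude** is a confounded predictor of TG and
the model is forced to exploit the **shift** — the same argument that
motivates the method on real data. The TG-dependent methylene shift is
0.01 ppm per mmol/L; that magnitude is a free parameter of the simulator,
not an empirical estimate (real spectra show the shift qualitatively, not
as a printed rate). Additive Gaussian noise is 2 % of each spectrum's
maximum (SNR ≈ 50), and each spectrum receives a random axis jitter
(default Gaussian, σ = 0.008 ppm) that referencing must undo.

Glucose doublet geometry: the splitting (±0.004 ppm ≈ 3.8 Hz at 500 MHz)
is combined with γ = 0.008 ppm so the summed doublet is single-peaked
exactly at 5.23 — two Lorentzians at ±d merge into one maximum only when
γ > √3·d; a narrower linewidth would put two horns around the anchor and
make peak referencing ill-posed.

Determinism: a config (seed included, and mandatory) reproduces a dataset
bit-for-bit. All random draws are made unconditionally and then scaled, so
two configs differing only in noise/jitter magnitude share their TG and
background draws under the same seed — which is what makes the
jitter-robustness comparison in the tests a paired comparison.

### What the simulator does not model

Physically rigorous lipoprotein NMR (diffusion-dependent lineshapes,
susceptibility effects, particle-size distributions), baseline drift
(available via the `baseline_drift` config knob, off by default), the EDTA and
amino-acid signals of real plasma, within-class compositional variation of
lipoprotein resonances, and reference-method error in y (the simulator's y
is exact). Consequently passing tests demonstrate the pipeline's
correctness and its behaviour under the *modelled* error sources; they do
not certify accuracy on clinical spectra, whose nonidealities are broader.
Simulated performance (r² ≈ 0.97 at n = 153) is accordingly somewhat better
than what real plasma calibrations reach (r² ≈ 0.9).

### One known limitation of the mechanism

The spectral response is nonlinear in TG (the shift enters through the
lineshape and multiplies amplitude), so even noiseless simulated data have
a linear-model ceiling: LOOCV r² plateaus near 0.986 regardless of
component count. This is intrinsic to a linear calibration of a shifting
peak and is visible in the tests as the noiseless-identifiability bound.

## Problem sizes and defaults

Default study conditions: n = 153 samples, grid 0.0–5.8 ppm at 0.002 ppm,
A = 3 components, k = 20 intervals, methylene interval 1.05–1.4 ppm. The
acceptance script runs a single seed of that study (≈ 6 s); the test
suite's simulation study repeats it over 10 seeds. Unit tests use smaller
grids (e.g. 0.5–2.0 ppm at 751 points) where the anchor region is not
needed.

## Design choices made where the design was open

- ppm axes are stored strictly descending and all region bounds are in
  ppm, never column indices; region cropping uses closed intervals.
- Linear interpolation (not splines) for regridding: spectra are densely
  sampled relative to linewidths, and linear interpolation is monotone,
  exact on piecewise-linear signals, and idempotent.
- CSV is the canonical exchange format; JCAMP-DX is read-only, AFFN-encoded
  tables only (compressed ASDF encodings are rejected with a clear error);
  vendor raw FID directories are out of scope since time-domain processing
  happens in spectrometer software.
- The full-spectrum analysis region defaults to 0.0–5.8 ppm (configurable)
  — the lipid + carbohydrate window of a plasma spectrum.
- r² is quoted as Pearson² of CV predictions vs measured; `r2_residual`
  carries the 1 − SSE/SST alternative for completeness.
- No train/test split beyond LOOCV, no k-fold variants, no outlier
  diagnostics (Hotelling T², Q residuals) — deliberately minimal scope.
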