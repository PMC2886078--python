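"""Leave-one-out cross-validation and calibration performance metrics.

Every reported model is validated by full leave-one-sample-out-at-a-time
cross-validation: each sample is predicted once, by a model fitted (with
centering recomputed) on the remaining n−1 samples, and all metrics are
computed from those held-out predictions.  The headline metrics are

* RMSECV — root-mean-square error of the cross-validated predictions, in
  mmol/L, directly comparable to the reference method's own uncertainty;
* R² — the squared Pearson correlation between cross-validated and measured
  values (the convention of chemometric calibration reports, where R and R²
  are quoted as a consistent pair); the 1 − SSE/SST variant is reported
  alongside as ``r2_residual``;
* the predicted-vs-measured least-squares line, whose slope/intercept are
  compared against the ideal identity line y = x.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pls import fit_pls, predict
from .spectra import SpectralDataset

__all__ = [
    "CVResult",
    "loocv_pls",
    "fit_identity_line",
    "save_cv_result",
]


@dataclass
class CVResult:
    """Cross-validated performance of one calibration model."""

    y_measured: np.ndarray
    y_cv: np.ndarray
    rmsecv: float
    r2: float
    r: float
    slope: float
    intercept: float
    n_components: int
    r2_residual: float = float("nan")
    sample_ids: list[str] | None = None
    region: tuple[float, float] | None = None

    @property
    def n_samples(self) -> int:
        return self.y_measured.size


def fit_identity_line(y_cv: np.ndarray, y_measured: np.ndarray) -> tuple[float, float]:
    """Least-squares line of predicted on measured values.

    Returns (slope, intercept) of ``y_cv ≈ slope · y_measured + intercept``,
    for comparison against the ideal target line y = x.
    """
    y_cv = np.asarray(y_cv, dtype=float)
    y_measured = np.asarray(y_measured, dtype=float)
    if y_cv.shape != y_measured.shape or y_cv.ndim != 1 or y_cv.size < 2:
        raise ValueError("need two same-length 1-D arrays with n >= 2")
    if np.ptp(y_measured) == 0:
        raise ValueError("measured values have zero variance; line is undefined")
    slope, intercept = np.polyfit(y_measured, y_cv, 1)
    return float(slope), float(intercept)


def _metrics(y_measured: np.ndarray, y_cv: np.ndarray, n_components: int,
             sample_ids=None, region=None) -> CVResult:
    resid = y_measured - y_cv
    rmsecv = float(np.sqrt(np.mean(resid**2)))
    r = float(np.corrcoef(y_measured, y_cv)[0, 1])
    slope, intercept = fit_identity_line(y_cv, y_measured)
    sst = float(np.sum((y_measured - y_measured.mean()) ** 2))
    r2_residual = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else float("nan")
    return CVResult(
        y_measured=y_measured,
        y_cv=y_cv,
        rmsecv=rmsecv,
        r2=r * r,
        r=r,
        slope=slope,
        intercept=intercept,
        n_components=n_components,
        r2_residual=r2_residual,
        sample_ids=sample_ids,
        region=region,
    )


def loocv_pls(dataset: SpectralDataset, n_components: int) -> CVResult:
    """Full leave-one-sample-out cross-validation of a PLS1 calibration.

    For each sample i a model is fitted on the other n−1 samples — centering
    included, so no information from the held-out sample leaks into the
    training means — and sample i is predicted once.  Metrics are computed
    from the n held-out predictions; the result is invariant to sample order.
    """
    if dataset.y is None:
        raise ValueError("dataset has no reference values; cannot cross-validate")
    n = dataset.n_samples
    A = int(n_components)
    if n < A + 2:
        raise ValueError(f"LOOCV with {A} components needs n >= {A + 2}, got n={n}")
    y_cv = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        model = fit_pls(dataset.X[train], dataset.y[train], A)
        y_cv[i] = predict(model, dataset.X[i])[0]
    region = (float(dataset.ppm.min()), float(dataset.ppm.max()))
    return _metrics(dataset.y.copy(), y_cv, A, list(dataset.sample_ids), region)


def save_cv_result(result: CVResult, json_path=None, csv_path=None) -> None:
    """Serialize a CVResult to JSON and/or a per-sample predictions CSV."""
    if json_path is not None:
        doc = {
            "n_samples": int(result.n_samples),
            "n_components": int(result.n_components),
            "region_ppm": None if result.region is None else list(result.region),
            "rmsecv_mmol_L": result.rmsecv,
            "r2": result.r2,
            "r": result.r,
            "r2_residual": result.r2_residual,
            "identity_line": {"slope": result.slope, "intercept_mmol_L": result.intercept},
        }
        Path(json_path).write_text(json.dumps(doc, indent=2))
    if csv_path is not None:
        ids = result.sample_ids or [str(i) for i in range(result.n_samples)]
        lines = ["sample_id,tg_measured,tg_cv"]
        lines += [
            f"{s},{m!r},{p!r}"
            for s, m, p in zip(ids, result.y_measured, result.y_cv)
        ]
        Path(csv_path).write_text("\n".join(lines) + "\n")
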