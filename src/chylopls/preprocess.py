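"""Preprocessing between raw spectra and the regression matrix.

Three steps, in the order the pipeline applies them:

1. chemical-shift referencing — anchor each spectrum on the α-D-glucose
   anomeric proton doublet at 5.23 ppm, correcting sample-to-sample axis
   drift so that intensity columns are comparable across samples;
2. region cropping — restrict to the spectral region of interest in ppm;
3. mean centering — subtract per-column means from X and the mean from y
   before PLS, so that the first PLS weight vector is proportional to the
   covariance of each spectral variable with y.

Only centering is y-dependent, so within cross-validation it is the only
step recomputed per training fold; referencing and cropping act sample-wise
and are applied once, globally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SpectralDataset, Spectrum, resample_to_grid

__all__ = [
    "CenteringState",
    "ReferencingError",
    "reference_to_anchor",
    "reference_dataset",
    "crop",
    "mean_center",
    "DEFAULT_ANCHOR_PPM",
    "DEFAULT_ANCHOR_HALFWIDTH",
    "DEFAULT_REGION",
]

#: Anomeric proton of α-D-glucose, the internal chemical-shift anchor.
DEFAULT_ANCHOR_PPM = 5.23
#: Half-width of the argmax search window around the anchor, ppm.
DEFAULT_ANCHOR_HALFWIDTH = 0.10
#: Default analysis region (lo, hi) in ppm: the lipid + sugar region.
DEFAULT_REGION = (0.0, 5.8)


class ReferencingError(ValueError):
    """The anchor peak could not be located; the spectrum is flagged."""


@dataclass
class CenteringState:
    """Column means of X and mean of y subtracted before PLS.

    Stored so a fitted model can center new spectra identically and report
    predictions back on the original mmol/L scale.
    """

    x_mean: np.ndarray
    y_mean: float

    def __post_init__(self) -> None:
        self.x_mean = np.asarray(self.x_mean, dtype=float)
        self.y_mean = float(self.y_mean)
        if not (np.all(np.isfinite(self.x_mean)) and np.isfinite(self.y_mean)):
            raise ValueError("centering state contains non-finite values")

    def center_X(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) - self.x_mean

    def uncenter_y(self, yc: np.ndarray) -> np.ndarray:
        return np.asarray(yc, dtype=float) + self.y_mean


def _peak_top_centroid(ppm: np.ndarray, intensity: np.ndarray, k: int,
                       top_fraction: float = 0.5) -> float:
    """Sub-grid peak position: intensity-weighted centroid of the contiguous
    run of points around index ``k`` that stay above ``top_fraction`` of the
    peak maximum.

    A bare argmax is quantized to the grid and, on a broad-topped peak,
    wanders with the noise of a single point; averaging the whole peak top
    localizes the resonance to a fraction of a grid step.  Restricting to
    the *contiguous* above-threshold run keeps neighbouring resonances
    (e.g. the olefinic band next to the glucose anchor) out of the centroid.
    """
    thr = top_fraction * intensity[k]
    lo = k
    while lo > 0 and intensity[lo - 1] >= thr:
        lo -= 1
    hi = k
    while hi < intensity.size - 1 and intensity[hi + 1] >= thr:
        hi += 1
    w = intensity[lo : hi + 1] - thr
    if w.sum() <= 0:
        return float(ppm[k])
    return float(np.sum(ppm[lo : hi + 1] * w) / w.sum())


def reference_to_anchor(
    spectrum: Spectrum,
    anchor_ppm: float = DEFAULT_ANCHOR_PPM,
    search_halfwidth: float = DEFAULT_ANCHOR_HALFWIDTH,
) -> Spectrum:
    """Shift the ppm axis so the anchor peak sits at ``anchor_ppm``.

    The anchor resonance is located as the maximum intensity within
    ``anchor_ppm ± search_halfwidth`` (the anomeric glucose doublet dominates
    this window in plasma spectra), refined to sub-grid precision by the
    centroid of the peak's top (see :func:`_peak_top_centroid`).  The axis is
    translated so that position lands at ``anchor_ppm``, then the spectrum is
    resampled back onto its original grid so that datasets stay
    column-aligned across samples.  Points shifted in from beyond an edge
    take the edge intensity (the shifts involved are a few grid steps at the
    spectrum's extremes, which are baseline).

    Raises
    ------
    ReferencingError
        If the window lies outside the spectrum or contains no maximum above
        the spectrum's median intensity (e.g. a flat or empty window), so a
        failed spectrum is flagged rather than silently mis-referenced.
    """
    lo, hi = anchor_ppm - search_halfwidth, anchor_ppm + search_halfwidth
    if hi > spectrum.ppm[0] + 1e-12 or lo < spectrum.ppm[-1] - 1e-12:
        raise ReferencingError(
            f"anchor window [{lo:g}, {hi:g}] ppm outside spectrum range "
            f"[{spectrum.ppm[-1]:g}, {spectrum.ppm[0]:g}] ppm"
        )
    mask = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    if not mask.any():
        raise ReferencingError("anchor window contains no grid points")
    window = spectrum.intensity[mask]
    if window.max() <= np.median(spectrum.intensity):
        raise ReferencingError(
            f"no anchor peak above the spectrum's median intensity in "
            f"[{lo:g}, {hi:g}] ppm for sample '{spectrum.sample_id}'"
        )
    peak_ppm = _peak_top_centroid(spectrum.ppm[mask], window, int(np.argmax(window)))
    delta = anchor_ppm - peak_ppm
    if abs(delta) < 1e-9:  # below any meaningful shift; avoid pointless resampling
        return spectrum
    shifted = Spectrum(spectrum.ppm + delta, spectrum.intensity, spectrum.sample_id, dict(spectrum.meta))
    # back onto the original grid; np.interp holds edge values beyond range
    asc = np.interp(
        spectrum.ppm[::-1], shifted.ppm[::-1], shifted.intensity[::-1]
    )[::-1]
    out = Spectrum(spectrum.ppm.copy(), asc, spectrum.sample_id, dict(spectrum.meta))
    out.meta["reference_shift_ppm"] = float(delta)
    return out


def reference_dataset(
    dataset: SpectralDataset,
    anchor_ppm: float = DEFAULT_ANCHOR_PPM,
    search_halfwidth: float = DEFAULT_ANCHOR_HALFWIDTH,
) -> SpectralDataset:
    """Apply :func:`reference_to_anchor` to every row of a dataset."""
    rows = [
        reference_to_anchor(dataset.spectrum(i), anchor_ppm, search_halfwidth).intensity
        for i in range(dataset.n_samples)
    ]
    return SpectralDataset(
        ppm=dataset.ppm.copy(),
        X=np.vstack(rows),
        sample_ids=list(dataset.sample_ids),
        y=None if dataset.y is None else dataset.y.copy(),
        meta=dataset.meta,
    )


def crop(dataset: SpectralDataset, lo_ppm: float, hi_ppm: float) -> SpectralDataset:
    """Keep columns with ``lo_ppm ≤ ppm ≤ hi_ppm`` (closed interval)."""
    if not lo_ppm < hi_ppm:
        raise ValueError(f"need lo_ppm < hi_ppm, got [{lo_ppm:g}, {hi_ppm:g}]")
    mask = (dataset.ppm >= lo_ppm) & (dataset.ppm <= hi_ppm)
    if not mask.any():
        raise ValueError(
            f"crop region [{lo_ppm:g}, {hi_ppm:g}] ppm contains no grid points "
            f"of the axis range [{dataset.ppm[-1]:g}, {dataset.ppm[0]:g}] ppm"
        )
    if mask.sum() < 2:
        raise ValueError(f"crop region [{lo_ppm:g}, {hi_ppm:g}] ppm keeps fewer than 2 points")
    return SpectralDataset(
        ppm=dataset.ppm[mask].copy(),
        X=dataset.X[:, mask].copy(),
        sample_ids=list(dataset.sample_ids),
        y=None if dataset.y is None else dataset.y.copy(),
        meta=dataset.meta,
    )


def mean_center(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, CenteringState]:
    """Subtract column means from X and the mean from y.

    Returns the centered matrices and a :class:`CenteringState` holding the
    subtracted means, so the transformation can be applied to new data and
    inverted exactly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an n×p matrix with n >= 2 to mean-center")
    if y.shape != (X.shape[0],):
        raise ValueError("y length does not match rows of X")
    state = CenteringState(x_mean=X.mean(axis=0), y_mean=float(y.mean()))
    return X - state.x_mean, y - state.y_mean, state
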