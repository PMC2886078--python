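"""NIPALS PLS1 regression — the calibration model ``y = Xb``.

Partial least squares extracts latent factors that maximize covariance
between the spectral matrix X and the reference values y.  On mean-centered
data the first weight vector is proportional to ``Xc' yc``, i.e. to the
per-variable covariance of spectral intensity with the analyte — this is the
property that makes PLS a covariance-guided (supervised) projection, and it
is asserted to machine precision in the test suite.

The classical NIPALS PLS1 recursion with X-deflation only is used:

    for each component a = 1..A:
        w_a = X' y / ||X' y||         (unit-norm weight)
        t_a = X w_a                   (score)
        p_a = X' t_a / (t_a' t_a)     (X loading)
        q_a = y' t_a / (t_a' t_a)     (y loading)
        X  <- X - t_a p_a'            (deflation)

and the regression vector on the centered scale is assembled as
``b = W (P'W)^{-1} q``.  At A = rank(Xc) this reproduces the least-squares
solution; at small A it is the low-rank regularized fit used in
chemometric calibration.  Everything is deterministic — there is no random
initialization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import CenteringState, mean_center

__all__ = [
    "PLSModel",
    "fit_pls",
    "predict",
    "regression_coefficient_profile",
    "save_model_json",
    "load_model_json",
    "DEFAULT_N_COMPONENTS",
]

#: Default number of latent variables; small calibrations of a single
#: analyte rarely support more without overfitting.
DEFAULT_N_COMPONENTS = 3

_MODEL_FORMAT_VERSION = 1


@dataclass
class PLSModel:
    """A fitted PLS1 calibration model.

    Attributes
    ----------
    n_components
        Number of latent variables A.
    centering
        Column means of the training X and mean of training y.
    W, P, T, q
        Weights (p×A), X-loadings (p×A), training scores (n×A) and
        y-loadings (A,) of the NIPALS decomposition.
    b, intercept
        Regression vector on the centered scale and the intercept that puts
        predictions ``X_new @ b + intercept`` back on the original mmol/L
        scale.
    ppm
        The (descending) ppm axis of the training columns, or None for
        non-spectral X.
    region
        (lo, hi) ppm bounds the model was trained on, or None.
    """

    n_components: int
    centering: CenteringState
    W: np.ndarray
    P: np.ndarray
    T: np.ndarray
    q: np.ndarray
    b: np.ndarray
    intercept: float
    ppm: np.ndarray | None = None
    region: tuple[float, float] | None = None

    @property
    def n_features(self) -> int:
        return self.b.size


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = DEFAULT_N_COMPONENTS,
    ppm: np.ndarray | None = None,
) -> PLSModel:
    """Fit a PLS1 model on mean-centered data by NIPALS.

    Parameters
    ----------
    X, y
        Training matrix (n×p) and reference values (n,), finite, with y of
        nonzero variance.
    n_components
        Number of latent variables A, with ``1 <= A <= min(n-1, p)``.
    ppm
        Optional ppm axis of the columns, kept for coefficient reporting.

    Notes
    -----
    Weight vectors are unit-norm with the sign fixed so the largest-magnitude
    element is positive, making the factorization deterministic across
    platforms.  If X deflates to (numerically) zero before A components are
    extracted, extraction stops early with a warning instead of dividing by
    a vanishing norm.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError(f"y must have length {n}, got {y.shape}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    A = int(n_components)
    if A < 1:
        raise ValueError("n_components must be >= 1")
    if A > min(n - 1, p):
        raise ValueError(
            f"n_components={A} exceeds min(n-1, p) = {min(n - 1, p)} for n={n}, p={p}"
        )
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance; nothing to calibrate")

    Xc, yc, centering = mean_center(X, y)
    Xd = Xc.copy()
    x_norm0 = np.linalg.norm(Xc)

    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    q = np.zeros(A)
    n_extracted = 0
    for a in range(A):
        if np.linalg.norm(Xd) < 1e-12 * max(x_norm0, 1.0):
            warnings.warn(
                f"X deflated to zero after {a} components; "
                f"stopping early (requested {A})",
                stacklevel=2,
            )
            break
        w = Xd.T @ yc
        w_norm = np.linalg.norm(w)
        if w_norm < 1e-14 * max(np.linalg.norm(yc), 1.0) or w_norm == 0.0:
            warnings.warn(
                f"residual X'y vanished after {a} components; "
                f"stopping early (requested {A})",
                stacklevel=2,
            )
            break
        w = w / w_norm
        if w[np.argmax(np.abs(w))] < 0:  # deterministic sign convention
            w = -w
        t = Xd @ w
        tt = t @ t
        pa = Xd.T @ t / tt
        qa = yc @ t / tt
        Xd = Xd - np.outer(t, pa)
        W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa
        n_extracted += 1

    if n_extracted == 0:
        raise ValueError("no PLS component could be extracted (X'y is zero)")
    W, P, T, q = W[:, :n_extracted], P[:, :n_extracted], T[:, :n_extracted], q[:n_extracted]

    # b = W (P'W)^{-1} q; P'W is upper triangular with unit-ish diagonal
    b = W @ np.linalg.solve(P.T @ W, q)
    intercept = centering.y_mean - float(centering.x_mean @ b)
    region = None
    if ppm is not None:
        ppm = np.asarray(ppm, dtype=float)
        if ppm.shape != (p,):
            raise ValueError("ppm axis length does not match columns of X")
        region = (float(ppm.min()), float(ppm.max()))
    return PLSModel(
        n_components=n_extracted,
        centering=centering,
        W=W,
        P=P,
        T=T,
        q=q,
        b=b,
        intercept=intercept,
        ppm=None if ppm is None else ppm.copy(),
        region=region,
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict reference values (mmol/L) for new spectra.

    ``X_new`` must have the model's column count (same ppm region and grid).
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.n_features:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns but the model was trained on "
            f"{model.n_features} (region {model.region})"
        )
    return X_new @ model.b + model.intercept


def fitted_values(model: PLSModel) -> np.ndarray:
    """The model's predictions on its own training scores."""
    return model.centering.y_mean + model.T @ model.q


def regression_coefficient_profile(model: PLSModel) -> tuple[np.ndarray, np.ndarray]:
    """Regression coefficients aligned to the model's ppm axis.

    Inspecting b against the spectrum shows *where* the calibration draws
    its information — for the chylomicron TG model, the high-ppm (left)
    flanks of the methylene and methyl peaks, where a small density-dependent
    shift of the resonance moves the most intensity.
    """
    if model.ppm is None:
        raise ValueError("model was fitted without a ppm axis")
    return model.ppm.copy(), model.b.copy()


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def save_model_json(model: PLSModel, path, provenance: dict | None = None) -> None:
    """Write a model to a versioned JSON document."""
    doc = {
        "format": "chylopls-pls-model",
        "version": _MODEL_FORMAT_VERSION,
        "n_components": int(model.n_components),
        "x_mean": model.centering.x_mean.tolist(),
        "y_mean": model.centering.y_mean,
        "W": model.W.tolist(),
        "P": model.P.tolist(),
        "q": model.q.tolist(),
        "b": model.b.tolist(),
        "intercept": model.intercept,
        "ppm": None if model.ppm is None else model.ppm.tolist(),
        "region": None if model.region is None else list(model.region),
        "provenance": provenance or {},
    }
    Path(path).write_text(json.dumps(doc))


def load_model_json(path) -> PLSModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "chylopls-pls-model":
        raise ValueError(f"{path}: not a chylopls PLS model document")
    if doc.get("version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported model format version {doc.get('version')}")
    ppm = None if doc["ppm"] is None else np.asarray(doc["ppm"], dtype=float)
    return PLSModel(
        n_components=int(doc["n_components"]),
        centering=CenteringState(np.asarray(doc["x_mean"], dtype=float), doc["y_mean"]),
        W=np.asarray(doc["W"], dtype=float),
        P=np.asarray(doc["P"], dtype=float),
        T=np.zeros((0, int(doc["n_components"]))),  # training scores not persisted
        q=np.asarray(doc["q"], dtype=float),
        b=np.asarray(doc["b"], dtype=float),
        intercept=float(doc["intercept"]),
        ppm=ppm,
        region=None if doc["region"] is None else tuple(doc["region"]),
    )
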