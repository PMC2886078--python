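"""Independent reference implementations used only to check the package.

These deliberately follow different computational paths from the library:
the PLS oracle predicts through score-space deflation of the query vector
(never forming a regression vector b), the least-squares oracle goes through
scipy's lstsq, and the LOOCV oracle is a from-scratch fold loop around the
score-space predictor.
"""

import numpy as np
import scipy.linalg


def ols_coefficients(X, y):
    """Minimum-norm least squares on mean-centered data via scipy lstsq."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    b, *_ = scipy.linalg.lstsq(Xc, yc)
    return b


def pls1_reference_predict(X_train, y_train, X_query, n_components):
    """Textbook PLS1 prediction via score-space deflation of the query rows.

    Fits the NIPALS recursion (with explicit y-deflation, which changes
    nothing mathematically) and predicts each query row by walking it
    through the same deflation sequence, accumulating q_a · t_a — no
    regression vector is ever formed.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    x_mean = X_train.mean(axis=0)
    y_mean = y_train.mean()
    E = X_train - x_mean
    f = y_train - y_mean
    Ws, Ps, qs = [], [], []
    for _ in range(n_components):
        w = E.T @ f
        w = w / np.linalg.norm(w)
        t = E @ w
        tt = t @ t
        p = E.T @ t / tt
        q = f @ t / tt
        E = E - np.outer(t, p)
        f = f - q * t
        Ws.append(w)
        Ps.append(p)
        qs.append(q)
    X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
    preds = []
    for row in X_query:
        e = row - x_mean
        acc = y_mean
        for w, p, q in zip(Ws, Ps, qs):
            t = e @ w
            acc += q * t
            e = e - t * p
        preds.append(acc)
    return np.asarray(preds)


def loocv_reference(X, y, n_components):
    """Brute-force leave-one-out loop, rebuilt from scratch per fold."""
    n = X.shape[0]
    out = np.empty(n)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        out[i] = pls1_reference_predict(X[keep], y[keep], X[i], n_components)[0]
    return out
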