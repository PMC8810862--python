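"""Ridge-penalized logistic regression via Newton iterations.

A minimal, allocation-light implementation: the SFFS x cross-validation loop
performs on the order of 10^5-10^6 small fits, so per-call overhead matters.
Features are standardized internally, the ridge penalty (applied to the
standardized weights, never the intercept) guarantees a finite optimum under
perfect separation, and coefficients are mapped back to the input scale.
scikit-learn's LogisticRegression serves as an independent cross-check in the
test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .errors import ConvergenceError

RIDGE_DEFAULT = 1e-6


def fit_logistic_raw(X: np.ndarray, y: np.ndarray,
                     ridge: float = RIDGE_DEFAULT,
                     max_iter: int = 100,
                     gtol: float = 1e-10,
                     strict: bool = False
                     ) -> tuple[np.ndarray, float, bool, int]:
    """Fit p(y=1|x) = sigmoid(b0 + x.w); returns (w, b0, converged, n_iter).

    Minimizes the negative log-likelihood plus 0.5 * ridge * ||w_std||^2 on
    standardized features.  With ``strict=True`` hitting the iteration cap
    raises :class:`ConvergenceError`; otherwise the capped estimate is
    returned with ``converged=False`` (under near-separation the optimum is
    approached slowly but the score ordering stabilizes early).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValueError("zero-variance feature in logistic design matrix")
    Z = (X - mu) / sd

    w = np.zeros(p + 1)  # [intercept, weights]
    pen = np.zeros(p + 1)
    pen[1:] = ridge

    def objective(wv):
        z = Z @ wv[1:] + wv[0]
        # log(1 + e^z) - y z, computed stably
        return (np.logaddexp(0.0, z) - y * z).sum() + 0.5 * ridge * (
            wv[1:] @ wv[1:])

    f = objective(w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = Z @ w[1:] + w[0]
        prob = expit(z)
        resid = prob - y
        g = np.empty(p + 1)
        g[0] = resid.sum()
        g[1:] = Z.T @ resid + ridge * w[1:]
        if np.abs(g).max() < gtol:
            converged = True
            break
        wgt = prob * (1.0 - prob)
        Zw = Z * wgt[:, None]
        H = np.empty((p + 1, p + 1))
        H[0, 0] = wgt.sum()
        H[0, 1:] = H[1:, 0] = Zw.sum(axis=0)
        H[1:, 1:] = Z.T @ Zw
        H[np.arange(1, p + 1), np.arange(1, p + 1)] += ridge
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # backtracking line search (Armijo)
        t = 1.0
        gd = g @ step
        while t > 1e-10:
            w_new = w - t * step
            f_new = objective(w_new)
            if f_new <= f - 1e-4 * t * gd:
                break
            t *= 0.5
        else:
            converged = True  # no descent possible: numerically at optimum
            break
        w, f_old, f = w_new, f, f_new
        if abs(f_old - f) <= 1e-12 * (1.0 + abs(f)):
            converged = True
            break
    if not converged and strict:
        raise ConvergenceError(
            "logistic fit did not converge",
            diagnostics={"n_iter": it, "grad_max": float(np.abs(g).max()),
                         "objective": float(f)})

    coef = w[1:] / sd
    intercept = float(w[0] - (w[1:] * mu / sd).sum())
    return coef, intercept, converged, it
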