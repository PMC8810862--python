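"""Independent oracles for feature-search and AUC checks.

These deliberately re-implement the search strategies (plain greedy,
exhaustive enumeration) around the same panel criterion, so the floating
search can be compared against them.
"""

from itertools import combinations

import numpy as np

from mirpanel._logistic import fit_logistic_raw
from mirpanel.diffexpr import mannwhitney_auc


def criterion(X: np.ndarray, y: np.ndarray, subset) -> float:
    cols = list(subset)
    coef, b0, _, _ = fit_logistic_raw(X[:, cols], y, max_iter=50, gtol=1e-8)
    return mannwhitney_auc(X[:, cols] @ coef + b0, y.astype(bool))


def greedy_forward(X: np.ndarray, y: np.ndarray, max_size: int):
    """Plain greedy forward selection; returns {size: (subset, criterion)}."""
    current: list[int] = []
    best = {}
    p = X.shape[1]
    for _ in range(max_size):
        scores = [(criterion(X, y, current + [j]), j)
                  for j in range(p) if j not in current]
        c, j = max(scores, key=lambda t: (t[0], -t[1]))
        current = current + [j]
        best[len(current)] = (tuple(sorted(current)), c)
    return best

def exhaustive_best(X: np.ndarray, y: np.ndarray, size: int):
    """Brute-force best subset of the given size."""
    best_c, best_s = -np.inf, None
    for subset in combinations(range(X.shape[1]), size):
        c = criterion(X, y, subset)
        if c > best_c:
            best_c, best_s = c, subset
    return best_s, best_c


def random_instance(rng, n=60, p=8, max_effect=1.0):
    """Class-shifted Gaussian features with random effect sizes."""
    y = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
    effects = rng.uniform(0, max_effect, p)
    X = rng.normal(size=(n, p)) + y[:, None] * effects[None, :]
    return X, y


def latent_pair_instance(rng, n=150, u_sd=2.5, decoy_effect=0.9,
                         n_noise=4):
    """Two features that are jointly informative but individually weak.

    ``x1 = u + v`` and ``x2 = -u + v`` share a strong nuisance component u
    that cancels in their sum, which recovers the latent signal v driving
    the labels.  A moderate decoy feature traps plain greedy forward
    selection at size two.  Columns: [decoy, x1, x2, noise...].
    """
    v = rng.normal(0, 1, n)
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-3.0 * v))).astype(float)
    u = rng.normal(0, u_sd, n)
    decoy = rng.normal(0, 1, n) + decoy_effect * y
    noise = rng.normal(size=(n, n_noise))
    X = np.column_stack([decoy, u + v, -u + v, noise])
    return X, y, (1, 2)
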