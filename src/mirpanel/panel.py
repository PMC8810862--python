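"""Multi-miRNA panel building and optimization.

Panels are grown by sequential forward floating search (SFFS) with a
logistic-regression risk model, inside a repeated source-stratified two-fold
cross-validation: in each iteration the training samples are split into two
equal groups (A and B) with each source x class cell divided evenly, SFFS is
run on one group and the refit panels are scored on the other, then the
roles are swapped.  The optimal panel size is the smallest size beyond which
the held-out AUC stops increasing significantly (plateau test), and the
final panel is the candidate of that size with the best combined
discovery / validation-1 performance.

The SFFS criterion is the training-fold AUC of the refit logistic model.
Best-of-size memory is seeded with a plain greedy forward sweep (sharing the
criterion cache), which guarantees SFFS never reports a worse panel than
greedy at any size; the floating removals can then only improve on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._logistic import RIDGE_DEFAULT, fit_logistic_raw
from .diffexpr import CANCER, mannwhitney_auc
from .errors import InsufficientGroupError

logger = logging.getLogger(__name__)


@dataclass
class CVPartition:
    iteration: int
    group_a: list[str]
    group_b: list[str]


@dataclass
class PanelModel:
    """Ordered miRNA subset with logistic coefficients on the log2 scale."""

    mirna_ids: list[str]
    coefficients: np.ndarray
    intercept: float
    cutoff: float | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mirna_ids": list(self.mirna_ids),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "cutoff": None if self.cutoff is None else float(self.cutoff),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PanelModel":
        return cls(mirna_ids=list(d["mirna_ids"]),
                   coefficients=np.asarray(d["coefficients"], dtype=float),
                   intercept=float(d["intercept"]),
                   cutoff=d.get("cutoff"),
                   metadata=d.get("metadata", {}))


def stratified_partition(samples: pd.DataFrame, rng: np.random.Generator,
                         iteration: int = 0) -> CVPartition:
    """Random split into two equal groups, stratified by source x class.

    Within every source x class cell the shuffled samples are assigned
    alternately; the odd-cell leftover goes to whichever group currently has
    fewer samples from that source (coin flip on ties), so per-cell and
    per-source imbalance never exceeds one.
    """
    group_a: list[str] = []
    group_b: list[str] = []
    for source, src_grp in samples.groupby("source_id", sort=True):
        balance = 0  # (#A - #B) within this source
        for _, cell in src_grp.groupby("class", sort=True):
            ids = sorted(cell["sample_id"])
            perm = rng.permutation(len(ids))
            shuffled = [ids[i] for i in perm]
            half = len(shuffled) // 2
            a_part, b_part = shuffled[:half], shuffled[half:2 * half]
            if len(shuffled) % 2:
                extra = shuffled[-1]
                if balance > 0:
                    b_part = b_part + [extra]
                    balance -= 1
                elif balance < 0:
                    a_part = a_part + [extra]
                    balance += 1
                elif rng.integers(2) == 0:
                    a_part = a_part + [extra]
                    balance += 1
                else:
                    b_part = b_part + [extra]
                    balance -= 1
            group_a.extend(a_part)
            group_b.extend(b_part)
    return CVPartition(iteration=iteration, group_a=sorted(group_a),
                       group_b=sorted(group_b))


def fit_logistic(log2_expr, labels, mirna_ids: list[str] | None = None,
                 ridge: float = RIDGE_DEFAULT,
                 strict: bool = False) -> PanelModel:
    """Ridge-penalized (lambda = 1e-6 on standardized features) logistic fit.

    ``log2_expr`` holds log2 normalized expression (DataFrame or array);
    ``labels`` are class labels ('cancer' positive) or 0/1.
    """
    if isinstance(log2_expr, pd.DataFrame):
        mirna_ids = list(log2_expr.columns)
        X = log2_expr.to_numpy(dtype=float)
    else:
        X = np.asarray(log2_expr, dtype=float)
        if mirna_ids is None:
            mirna_ids = [f"x{i}" for i in range(X.shape[1])]
    y = _binary_labels(labels)
    if y.sum() == 0 or y.sum() == len(y):
        raise InsufficientGroupError("need >= 1 sample per class")
    coef, intercept, converged, n_iter = fit_logistic_raw(
        X, y, ridge=ridge, strict=strict)
    return PanelModel(mirna_ids=mirna_ids, coefficients=coef,
                      intercept=intercept,
                      metadata={"converged": bool(converged),
                                "n_iter": int(n_iter),
                                "ridge": ridge})


def _binary_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        return (arr == CANCER).astype(float)
    return arr.astype(float)


def score(model: PanelModel, expr_row) -> float:
    """Risk score in [0, 1] for one sample of linear-scale expression."""
    vals = np.array([expr_row[m] for m in model.mirna_ids], dtype=float)
    z = model.intercept + model.coefficients @ np.log2(vals)
    return float(1.0 / (1.0 + np.exp(-z)))


def score_samples(model: PanelModel, norm_expr: pd.DataFrame) -> pd.Series:
    """Vectorized risk scores for a linear-scale expression matrix."""
    missing = [m for m in model.mirna_ids if m not in norm_expr.columns]
    if missing:
        raise KeyError(f"panel miRNAs missing from matrix: {missing}")
    X = np.log2(norm_expr[model.mirna_ids].to_numpy(dtype=float))
    z = model.intercept + X @ model.coefficients
    return pd.Series(1.0 / (1.0 + np.exp(-z)), index=norm_expr.index,
                     name="score")


class _Criterion:
    """Cached SFFS criterion: training AUC of the refit logistic model."""

    def __init__(self, X: np.ndarray, y: np.ndarray, ridge: float):
        self.X = X
        self.y = y
        self.yb = y.astype(bool)
        self.ridge = ridge
        self.cache: dict[frozenset, float] = {}
        self.failures = 0

    def __call__(self, subset: tuple[int, ...]) -> float:
        key = frozenset(subset)
        val = self.cache.get(key)
        if val is not None:
            return val
        try:
            Xs = self.X[:, subset]
            coef, b0, _, _ = fit_logistic_raw(Xs, self.y, ridge=self.ridge,
                                              max_iter=50, gtol=1e-8)
            val = mannwhitney_auc(Xs @ coef + b0, self.yb)
        except (ValueError, np.linalg.LinAlgError) as exc:
            self.failures += 1
            logger.debug("criterion failed for subset %s: %s", subset, exc)
            val = -np.inf
        self.cache[key] = val
        return val


def _best_addition(crit, current: list[int], candidates: list[int]):
    best_c, best_j = -np.inf, None
    for j in candidates:
        c = crit(tuple(current + [j]))
        if c > best_c:
            best_c, best_j = c, j
    return best_j, best_c


def sffs(pool: list[str], log2_expr, labels, max_size: int,
         ridge: float = RIDGE_DEFAULT) -> dict[int, tuple[list[str], float]]:
    """Best panel of every size 1..max_size by forward floating search.

    Returns {size: (sorted miRNA ids, criterion)}.  Ties are broken toward
    the candidate encountered first in lexicographic id order.
    """
    pool = sorted(pool)
    if isinstance(log2_expr, pd.DataFrame):
        X = log2_expr[pool].to_numpy(dtype=float)
    else:
        X = np.asarray(log2_expr, dtype=float)
    y = _binary_labels(labels)
    if max_size > len(pool):
        raise ValueError("max_size exceeds pool size")
    crit = _Criterion(X, y, ridge)
    all_idx = list(range(len(pool)))
    # canonical representative per exact duplicate column: a duplicate of a
    # selected feature adds no information and is never offered forward
    canon: dict[bytes, int] = {}
    rep = [canon.setdefault(X[:, j].tobytes(), j) for j in all_idx]

    def candidates_for(current: list[int]) -> list[int]:
        taken = {rep[i] for i in current}
        return [j for j in all_idx if j not in current
                and rep[j] not in taken]

    best: dict[int, tuple[float, tuple[int, ...]]] = {}

    def update(subset: tuple[int, ...], c: float) -> bool:
        s = len(subset)
        if s not in best or c > best[s][0]:
            best[s] = (c, tuple(sorted(subset)))
            return True
        return False

    # greedy forward sweep seeds the best-of-size memory (dominance guarantee)
    current: list[int] = []
    for _ in range(max_size):
        j, c = _best_addition(crit, current, candidates_for(current))
        current.append(j)
        update(tuple(current), c)

    # forward floating dynamics
    current = []
    guard = 0
    while len(current) < max_size:
        guard += 1
        if guard > 50 * max_size:
            logger.warning("SFFS iteration guard tripped; stopping early")
            break
        j, c = _best_addition(crit, current, candidates_for(current))
        current.append(j)
        update(tuple(current), c)
        if c < best[len(current)][0]:
            current = list(best[len(current)][1])
        # conditional (floating) removals
        while len(current) > 2:
            best_rm, best_rc = None, -np.inf
            for r in current:
                sub = tuple(i for i in current if i != r)
                cr = crit(sub)
                if cr > best_rc:
                    best_rc, best_rm = cr, r
            if best_rc > best[len(current) - 1][0]:
                current = [i for i in current if i != best_rm]
                update(tuple(current), best_rc)
            else:
                break

    return {s: ([pool[i] for i in ids], c)
            for s, (c, ids) in sorted(best.items())}


def crossvalidate_panels(norm_expr: pd.DataFrame, samples: pd.DataFrame,
                         pool: list[str], n_iter: int = 200,
                         sizes=range(2, 13), seed: int = 0,
                         ridge: float = RIDGE_DEFAULT) -> pd.DataFrame:
    """Repeated stratified two-fold cross-validation of SFFS panels.

    Two records per size per iteration (Group A training, then Group B).
    Fully reproducible from the master seed: each iteration draws its
    partition from an independent substream.
    """
    sizes = sorted(sizes)
    max_size = max(sizes)
    if len(pool) < max_size:
        raise ValueError("pool smaller than the largest panel size")
    samples = samples[samples["sample_id"].isin(norm_expr.index)]
    pool = sorted(pool)
    X_all = np.log2(norm_expr[pool].to_numpy(dtype=float))
    y_all = _binary_labels(samples.set_index("sample_id")
                           .loc[norm_expr.index, "class"])
    row_of = {sid: i for i, sid in enumerate(norm_expr.index)}

    records = []
    streams = np.random.SeedSequence(seed).spawn(n_iter)
    for it in range(n_iter):
        rng = np.random.default_rng(streams[it])
        part = stratified_partition(samples, rng, iteration=it)
        idx_a = np.array([row_of[s] for s in part.group_a])
        idx_b = np.array([row_of[s] for s in part.group_b])
        for fold, (tr, te) in (("A_train", (idx_a, idx_b)),
                               ("B_train", (idx_b, idx_a))):
            best = sffs(pool, X_all[tr], y_all[tr], max_size, ridge=ridge)
            Xtr, ytr = X_all[tr], y_all[tr]
            Xte, yte = X_all[te], y_all[te]
            col_of = {m: i for i, m in enumerate(pool)}
            for s in sizes:
                ids, _ = best[s]
                cols = [col_of[m] for m in ids]
                try:
                    coef, b0, _, _ = fit_logistic_raw(
                        Xtr[:, cols], ytr, ridge=ridge, max_iter=50,
                        gtol=1e-8)
                except (ValueError, np.linalg.LinAlgError) as exc:
                    logger.warning("iteration %d fold %s size %d skipped: %s",
                                   it, fold, s, exc)
                    continue
                train_auc = mannwhitney_auc(Xtr[:, cols] @ coef + b0,
                                            ytr.astype(bool))
                test_auc = mannwhitney_auc(Xte[:, cols] @ coef + b0,
                                           yte.astype(bool))
                records.append((it, fold, s, ",".join(ids),
                                train_auc, test_auc))
    return pd.DataFrame(records, columns=["iteration", "fold", "panel_size",
                                          "mirna_ids", "train_auc",
                                          "test_auc"])


def optimal_size(cv: pd.DataFrame, alpha: float = 0.001) -> int:
    """Smallest size s whose increase to s+1 is no longer significant.

    Two-sided t-test on the held-out AUC distributions of consecutive sizes;
    an increase counts only when the larger panel's mean is higher and
    p < alpha.  If every step is significant the largest size is returned.
    """
    sizes = sorted(cv["panel_size"].unique())
    if len(sizes) < 2:
        raise ValueError("need at least 2 panel sizes")
    by_size = {s: cv.loc[cv["panel_size"] == s, "test_auc"].to_numpy()
               for s in sizes}
    for s in sizes:
        if len(by_size[s]) < 2:
            raise ValueError(f"fewer than 2 records for size {s}")
    for s, s_next in zip(sizes[:-1], sizes[1:]):
        a, b = by_size[s], by_size[s_next]
        t, p = stats.ttest_ind(b, a, equal_var=True)
        significant = (np.isfinite(p) and p < alpha
                       and b.mean() > a.mean())
        if not significant:
            return int(s)
    return int(sizes[-1])


def select_final_panel(cv: pd.DataFrame, size: int,
                       disc_expr: pd.DataFrame, disc_labels,
                       val1_expr: pd.DataFrame, val1_labels,
                       ridge: float = RIDGE_DEFAULT) -> PanelModel:
    """Choose the best candidate panel of the given size.

    Every distinct panel of that size seen during cross-validation is refit
    on the discovery cohort and scored on discovery and validation 1; the
    panel maximizing the mean of the two AUCs (ties: lexicographic ids) is
    refit on the combined cohorts and returned.
    """
    candidates = sorted({tuple(sorted(p.split(",")))
                         for p in cv.loc[cv["panel_size"] == size,
                                         "mirna_ids"]})
    if not candidates:
        raise ValueError(f"no candidate panels of size {size}")
    yd = _binary_labels(disc_labels)
    yv = _binary_labels(val1_labels)
    best_key, best_panel = None, None
    for ids in candidates:
        Xd = np.log2(disc_expr[list(ids)].to_numpy(dtype=float))
        Xv = np.log2(val1_expr[list(ids)].to_numpy(dtype=float))
        # screening fits use the same loose cap as the CV criterion; only
        # the winning panel gets the full-precision refit below
        coef, b0, _, _ = fit_logistic_raw(Xd, yd, ridge=ridge,
                                          max_iter=50, gtol=1e-8)
        auc_d = mannwhitney_auc(Xd @ coef + b0, yd.astype(bool))
        auc_v = mannwhitney_auc(Xv @ coef + b0, yv.astype(bool))
        key = (-(auc_d + auc_v) / 2.0, ids)
        if best_key is None or key < best_key:
            best_key, best_panel = key, ids
    ids = list(best_panel)
    X = np.vstack([np.log2(disc_expr[ids].to_numpy(dtype=float)),
                   np.log2(val1_expr[ids].to_numpy(dtype=float))])
    y = np.concatenate([yd, yv])
    coef, b0, converged, n_iter = fit_logistic_raw(X, y, ridge=ridge)
    return PanelModel(mirna_ids=ids, coefficients=coef, intercept=b0,
                      metadata={"mean_train_auc": float(-best_key[0]),
                                "converged": bool(converged),
                                "n_iter": int(n_iter), "ridge": ridge})
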