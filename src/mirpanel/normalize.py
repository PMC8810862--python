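"""Reference-miRNA stability selection and normalization.

Two stability measures are re-implemented:

* geNORM M: for candidate j, the mean over all other candidates k of the
  standard deviation across samples of log2(x_j / x_k); candidates are
  iteratively excluded (highest M first) until two remain.
* NormFinder-style rho: after removing the per-sample level (centering each
  sample across candidates), rho_g = mean over groups i of
  |d_gi| + sqrt(w_gi / n_i), where d_gi is the group-mean deviation of
  candidate g and w_gi its within-group variance.  This is a simplified
  estimator of the published model: it preserves the ranking behaviour
  without the original's small-sample variance corrections.

Normalization divides each sample's values by the geometric mean of its
reference-miRNA values, removing per-sample multiplicative distortion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientCandidatesError, InsufficientGroupError
from .quantify import FLAG_FLOORED, ExpressionMatrix

logger = logging.getLogger(__name__)

#: candidates must be detected (non-floored) in at least this fraction of samples
DETECTION_FRACTION = 0.9


@dataclass
class ReferenceSet:
    mirna_ids: list[str]
    selection_method: str = "consensus"


def candidate_pool(expr: ExpressionMatrix,
                   detection_fraction: float = DETECTION_FRACTION
                   ) -> list[str]:
    """miRNAs detected (non-floored) in at least ``detection_fraction`` of samples."""
    detected = (expr.flags != FLAG_FLOORED).mean(axis=0)
    return sorted(detected.index[detected >= detection_fraction])


def genorm_m(log_expr: pd.DataFrame) -> pd.Series:
    """geNORM stability M per candidate (columns of ``log_expr``).

    Computed from the candidate covariance matrix:
    SD(x_j - x_k) = sqrt(C_jj + C_kk - 2 C_jk), which is algebraically the
    pairwise log-ratio SD when ``log_expr`` holds log2 values.
    """
    if log_expr.shape[1] < 2:
        raise InsufficientCandidatesError("geNORM needs >= 2 candidates")
    if log_expr.shape[0] < 2:
        raise InsufficientCandidatesError("geNORM needs >= 2 samples")
    X = log_expr.to_numpy(dtype=float)
    C = np.cov(X, rowvar=False, ddof=1)
    d = np.diag(C)
    pairvar = np.maximum(d[:, None] + d[None, :] - 2.0 * C, 0.0)
    sd = np.sqrt(pairvar)
    k = sd.shape[0]
    m = (sd.sum(axis=1)) / (k - 1)  # diagonal is zero
    return pd.Series(m, index=log_expr.columns, name="genorm_m")


def genorm_rank(log_expr: pd.DataFrame
                ) -> tuple[pd.Series, pd.Series]:
    """Iterative geNORM exclusion.

    Repeatedly removes the least-stable candidate (highest M, ties broken by
    reverse-lexicographic id so the lexicographically smaller id survives)
    until two remain.  Returns

    * ranks: 1 = most stable; the final pair, which geNORM itself cannot
      separate, receives ranks 1 and 2 ordered by M in the final round;
    * pairwise variations V(n, n+1): the SD across samples of the difference
      between the log2 geometric means of the top-n and top-(n+1) sets.
    """
    cols = list(log_expr.columns)
    if len(cols) < 3:
        raise InsufficientCandidatesError("geNORM ranking needs >= 3 candidates")
    remaining = sorted(cols)
    exclusion_order: list[str] = []
    while len(remaining) > 2:
        m = genorm_m(log_expr[remaining])
        # highest M excluded first; on ties exclude the lexicographically
        # larger id so the smaller id survives
        worst_id = max(m.index[m == m.max()])
        exclusion_order.append(worst_id)
        remaining.remove(worst_id)
    m_final = genorm_m(log_expr[remaining])
    last_two = sorted(remaining, key=lambda c: (m_final[c], c))
    stability_order = last_two + exclusion_order[::-1]
    ranks = pd.Series({c: i + 1 for i, c in enumerate(stability_order)},
                      name="genorm_rank").reindex(cols)

    pairwise_v = {}
    X = log_expr
    for n in range(2, len(cols)):
        top_n = stability_order[:n]
        top_n1 = stability_order[:n + 1]
        gm_n = X[top_n].mean(axis=1)
        gm_n1 = X[top_n1].mean(axis=1)
        pairwise_v[f"V{n}/{n + 1}"] = float((gm_n - gm_n1).std(ddof=1))
    return ranks, pd.Series(pairwise_v, name="pairwise_variation")


def normfinder_stability(log_expr: pd.DataFrame,
                         class_labels: pd.Series | np.ndarray) -> pd.Series:
    """NormFinder-style stability rho per candidate (lower = more stable)."""
    if log_expr.shape[1] < 2:
        raise InsufficientCandidatesError("NormFinder needs >= 2 candidates")
    labels = np.asarray(class_labels)
    groups = np.unique(labels)
    for g in groups:
        if (labels == g).sum() < 2:
            raise InsufficientGroupError(
                f"group {g!r} has fewer than 2 samples")
    X = log_expr.to_numpy(dtype=float)
    # remove the per-sample level (RNA input / global content)
    X = X - X.mean(axis=1, keepdims=True)
    v = np.stack([X[labels == g].mean(axis=0) for g in groups])      # G x m
    w = np.stack([X[labels == g].var(axis=0, ddof=1) for g in groups])
    n = np.array([(labels == g).sum() for g in groups], dtype=float)
    d = v - v.mean(axis=0, keepdims=True)
    rho = (np.abs(d) + np.sqrt(w / n[:, None])).mean(axis=0)
    return pd.Series(rho, index=log_expr.columns, name="normfinder_rho")


def stability_table(log_expr: pd.DataFrame,
                    class_labels: pd.Series | np.ndarray) -> pd.DataFrame:
    """geNORM and NormFinder stability for every candidate column."""
    m = genorm_m(log_expr)
    ranks, _ = genorm_rank(log_expr)
    rho = normfinder_stability(log_expr, class_labels)
    return pd.DataFrame({"genorm_m": m, "genorm_rank": ranks,
                         "normfinder_rho": rho})


def select_references(stability: pd.DataFrame, k: int = 3) -> ReferenceSet:
    """Consensus selection: rank-sum of geNORM rank and NormFinder rank.

    Ties are broken by lexicographic miRNA id.
    """
    if k < 1:
        raise InsufficientCandidatesError("k must be >= 1")
    if k > len(stability):
        raise InsufficientCandidatesError(
            f"k={k} exceeds candidate count {len(stability)}")
    nf_rank = stability["normfinder_rho"].rank(method="min")
    score = stability["genorm_rank"] + nf_rank
    order = sorted(stability.index, key=lambda c: (score[c], c))
    return ReferenceSet(mirna_ids=order[:k], selection_method="consensus")


def normalize_expression(expr: ExpressionMatrix,
                         refs: ReferenceSet) -> ExpressionMatrix:
    """Divide each sample's values by the geometric mean of its references.

    Samples with a non-positive or missing reference value are excluded with
    a log entry.  Reference columns are retained.
    """
    values = expr.values
    for r in refs.mirna_ids:
        if r not in values.columns:
            raise InsufficientCandidatesError(f"reference {r} not in matrix")
    ref_vals = values[refs.mirna_ids]
    bad = (~np.isfinite(ref_vals) | (ref_vals <= 0)).any(axis=1)
    excluded = dict(expr.excluded_samples)
    for sid in values.index[bad]:
        excluded[sid] = "non-positive reference value"
        logger.warning("sample %s excluded from normalization", sid)
    keep = values.index[~bad]
    gm = np.exp2(np.log2(ref_vals.loc[keep]).mean(axis=1))
    norm = values.loc[keep].div(gm, axis=0)
    return ExpressionMatrix(values=norm, flags=expr.flags.loc[keep],
                            excluded_samples=excluded)
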