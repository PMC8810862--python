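"""Per-miRNA differential statistics and candidate selection.

Discovery-phase selection keeps markers with raw p below the threshold,
|log2FC| above the threshold and directional AUC above 0.5 (the AUC oriented
by the sign of the fold change, so a marker whose rank separation contradicts
its fold change is dropped).  Validation confirms candidates at a relaxed p
threshold with a consistent fold-change sign.  q-values (Benjamini-Hochberg)
are reported alongside; ``use_q`` switches selection to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientGroupError, UndefinedCorrelationError

CANCER = "cancer"


@dataclass
class CandidateSet:
    discovery_pass: list[str]
    validated: list[str] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)


def mannwhitney_auc(values: np.ndarray, is_case: np.ndarray) -> float:
    """P(random case value > random control value), ties counting 1/2."""
    r = stats.rankdata(values)
    n1 = int(is_case.sum())
    n0 = len(values) - n1
    if n1 == 0 or n0 == 0:
        raise InsufficientGroupError("both classes required for AUC")
    u = r[is_case].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def marker_stats(norm_expr: pd.DataFrame, labels: pd.Series | np.ndarray,
                 equal_var: bool = True) -> pd.DataFrame:
    """Per-miRNA log2FC, t-test p, BH q, and AUC (cancer vs control).

    ``norm_expr`` holds positive normalized abundances; statistics are
    computed on log2 values.  ``equal_var=True`` is the classical pooled
    t-test; ``False`` switches to Welch.
    """
    labels = np.asarray(labels)
    is_case = labels == CANCER
    n1, n0 = int(is_case.sum()), int((~is_case).sum())
    if n1 < 2 or n0 < 2:
        raise InsufficientGroupError("each class needs >= 2 samples")
    X = np.log2(norm_expr.to_numpy(dtype=float))
    lfc = X[is_case].mean(axis=0) - X[~is_case].mean(axis=0)
    t, p = stats.ttest_ind(X[is_case], X[~is_case], axis=0,
                           equal_var=equal_var)
    q = multipletests(p, method="fdr_bh")[1]
    r = stats.rankdata(X, axis=0)
    u = r[is_case].sum(axis=0) - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    return pd.DataFrame({
        "log2fc": lfc, "t_stat": t, "p_value": p, "q_value": q, "auc": auc,
        "n_cancer": n1, "n_control": n0,
    }, index=norm_expr.columns)


def select_candidates(stats_discovery: pd.DataFrame,
                      p_thresh: float = 0.01,
                      lfc_thresh: float = 0.5,
                      auc_thresh: float = 0.5,
                      use_q: bool = False) -> list[str]:
    """Discovery-phase filter: p < p_thresh, |log2FC| > lfc_thresh and
    directional AUC > auc_thresh (strict inequalities throughout)."""
    s = stats_discovery
    pcol = s["q_value"] if use_q else s["p_value"]
    directional_auc = np.where(s["log2fc"] > 0, s["auc"], 1.0 - s["auc"])
    keep = ((pcol < p_thresh)
            & (s["log2fc"].abs() > lfc_thresh)
            & (directional_auc > auc_thresh))
    return sorted(s.index[keep])


def validate_candidates(stats_validation: pd.DataFrame,
                        stats_discovery: pd.DataFrame,
                        discovery_pass: list[str],
                        p_thresh: float = 0.05,
                        lfc_thresh: float = 0.5,
                        use_q: bool = False) -> CandidateSet:
    """Confirm discovery candidates in the validation cohort.

    A candidate is validated when p < p_thresh, |log2FC| > lfc_thresh and
    the fold-change sign matches discovery; otherwise it is excluded with a
    reason.
    """
    validated, excluded = [], {}
    for m in discovery_pass:
        sv = stats_validation.loc[m]
        pv = sv["q_value"] if use_q else sv["p_value"]
        if pv >= p_thresh:
            excluded[m] = "not_significant"
        elif abs(sv["log2fc"]) <= lfc_thresh:
            excluded[m] = "small_fold_change"
        elif np.sign(sv["log2fc"]) != np.sign(
                stats_discovery.loc[m, "log2fc"]):
            excluded[m] = "sign_flip"
        else:
            validated.append(m)
    return CandidateSet(discovery_pass=list(discovery_pass),
                        validated=sorted(validated), excluded=excluded)


def fold_change_correlation(stats_a: pd.DataFrame, stats_b: pd.DataFrame,
                            mirnas: list[str]) -> tuple[float, float]:
    """Pearson correlation of the two cohorts' log2FC over ``mirnas``."""
    if len(mirnas) < 3:
        raise UndefinedCorrelationError("need >= 3 shared miRNAs")
    a = stats_a.loc[mirnas, "log2fc"].to_numpy()
    b = stats_b.loc[mirnas, "log2fc"].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedCorrelationError("zero variance in a log2FC vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def standardize_log2(norm_expr: pd.DataFrame) -> pd.DataFrame:
    """log2 values standardized per miRNA to zero mean (heat-map scale)."""
    X = np.log2(norm_expr.to_numpy(dtype=float))
    return pd.DataFrame(X - X.mean(axis=0, keepdims=True),
                        index=norm_expr.index, columns=norm_expr.columns)


def hierarchical_cluster(standardized: pd.DataFrame
                         ) -> tuple[list[str], list[str],
                                    np.ndarray, np.ndarray]:
    """Agglomerative clustering of both axes (Euclidean, average linkage).

    Returns (sample leaf order, miRNA leaf order, sample linkage, miRNA
    linkage).
    """
    X = standardized.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("clustering input contains non-finite values")
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("clustering needs >= 2 rows and >= 2 columns")
    link_samples = linkage(X, method="average", metric="euclidean")
    link_mirnas = linkage(X.T, method="average", metric="euclidean")
    sample_order = [standardized.index[i] for i in leaves_list(link_samples)]
    mirna_order = [standardized.columns[i] for i in leaves_list(link_mirnas)]
    return sample_order, mirna_order, link_samples, link_mirnas
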