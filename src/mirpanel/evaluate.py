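"""Held-out evaluation of a fixed panel model.

ROC/AUC with DeLong confidence intervals, the maximum-accuracy score cutoff,
sensitivity/specificity/accuracy with Wilson intervals, and performance
stratified by sample source (that source's cases vs its controls) and by
tumour stage (each stage's cases vs all of the cohort's controls, plus
early/late composites).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .diffexpr import CANCER, mannwhitney_auc
from .errors import InsufficientGroupError
from .panel import PanelModel, score_samples

logger = logging.getLogger(__name__)

EARLY_STAGES = ("0", "I", "II")
LATE_STAGES = ("III", "IV")


def _as_bool_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        return arr == CANCER
    return arr.astype(bool)


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve with thresholds at the distinct scores.

    Rows ordered from (0, 0) to (1, 1); the trapezoid area under the curve
    equals the Mann-Whitney statistic (asserted on every call).
    """
    scores = np.asarray(scores, dtype=float)
    pos = _as_bool_labels(labels)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise InsufficientGroupError("both classes required for a ROC curve")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], pos[order]
    # collapse tied scores into single threshold steps
    distinct = np.r_[np.diff(s) != 0, True]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    mw = mannwhitney_auc(scores, pos)
    assert abs(auc - mw) < 1e-10, "trapezoid AUC != Mann-Whitney AUC"
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})


def trapezoid_auc(scores, labels) -> float:
    roc = roc_points(scores, labels)
    return float(np.trapezoid(roc["tpr"], roc["fpr"]))


def _delong_auc_variance(pos_scores: np.ndarray,
                         neg_scores: np.ndarray) -> tuple[float, float]:
    """DeLong (1988) estimate of AUC and its sampling variance."""
    m, n = len(pos_scores), len(neg_scores)
    combined = np.concatenate([pos_scores, neg_scores])
    tz = stats.rankdata(combined)
    tx = stats.rankdata(pos_scores)
    ty = stats.rankdata(neg_scores)
    v01 = (tz[:m] - tx) / n          # structural components over cases
    v10 = 1.0 - (tz[m:] - ty) / m    # over controls
    auc = float(v01.mean())
    var = (np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n
           if m > 1 and n > 1 else 0.0)
    return auc, float(var)


def bootstrap_auc_ci(scores, labels, n_boot: int = 2000, seed: int = 0,
                     level: float = 0.95) -> tuple[float, float, float]:
    """Percentile bootstrap CI, resampling cases and controls separately."""
    scores = np.asarray(scores, dtype=float)
    pos = _as_bool_labels(labels)
    sp, sn = scores[pos], scores[~pos]
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        bp = sp[rng.integers(len(sp), size=len(sp))]
        bn = sn[rng.integers(len(sn), size=len(sn))]
        r = stats.rankdata(np.concatenate([bp, bn]))
        u = r[:len(bp)].sum() - len(bp) * (len(bp) + 1) / 2.0
        aucs[b] = u / (len(bp) * len(bn))
    lo, hi = np.quantile(aucs, [(1 - level) / 2, 1 - (1 - level) / 2])
    return mannwhitney_auc(scores, pos), float(lo), float(hi)


def auc_ci(scores, labels, method: str = "delong",
           level: float = 0.95, n_boot: int = 2000,
           seed: int = 0) -> tuple[float, float, float]:
    """AUC with a confidence interval (DeLong by default).

    Falls back to the seeded bootstrap when the DeLong variance degenerates
    to zero with a non-trivial AUC.
    """
    scores = np.asarray(scores, dtype=float)
    pos = _as_bool_labels(labels)
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise InsufficientGroupError("need >= 2 samples per class")
    if method == "bootstrap":
        return bootstrap_auc_ci(scores, labels, n_boot=n_boot, seed=seed,
                                level=level)
    auc, var = _delong_auc_variance(scores[pos], scores[~pos])
    if var == 0.0 and 0.0 < auc < 1.0:
        logger.info("degenerate DeLong variance; falling back to bootstrap")
        return bootstrap_auc_ci(scores, labels, n_boot=n_boot, seed=seed,
                                level=level)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return auc, float(max(0.0, auc - half)), float(min(1.0, auc + half))


def max_accuracy_cutoff(scores, labels
                        ) -> tuple[float, float, float, float]:
    """Cutoff maximizing (TP + TN) / N under the rule score >= cutoff => cancer.

    Thresholds are scanned at midpoints between adjacent distinct scores plus
    the two all-positive / all-negative extremes; accuracy ties resolve
    toward higher specificity.  Returns (cutoff, accuracy, sensitivity,
    specificity).
    """
    scores = np.asarray(scores, dtype=float)
    pos = _as_bool_labels(labels)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise InsufficientGroupError("both classes required")
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.r_[distinct[0] - 0.5, mids, distinct[-1] + 0.5]
    best = None
    for cut in candidates:
        pred = scores >= cut
        tp = int((pred & pos).sum())
        tn = int((~pred & ~pos).sum())
        acc = (tp + tn) / len(scores)
        sens = tp / n1
        spec = tn / n0
        key = (acc, spec, -cut)  # ties -> higher specificity, then lower cut
        if best is None or key > best[0]:
            best = (key, (float(cut), acc, sens, spec))
    return best[1]


def proportion_ci(successes: int, n: int, level: float = 0.95,
                  method: str = "wilson") -> tuple[float, float, float]:
    """Binomial proportion with a Wilson score interval."""
    if not (0 <= successes <= n) or n < 1:
        raise ValueError("need 0 <= successes <= n, n >= 1")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method=method)
    # the Wilson endpoints at k=0 and k=n are exactly 0 and 1; remove the
    # floating-point residue of the quadratic solution
    lo = 0.0 if successes == 0 else float(lo)
    hi = 1.0 if successes == n else float(hi)
    return successes / n, lo, hi


def _score_summary(values: np.ndarray) -> dict:
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return {"n": int(len(values)), "median": float(med),
            "q1": float(q1), "q3": float(q3)}


def stratified_eval(scores: pd.Series, samples: pd.DataFrame) -> dict:
    """Per-source and per-stage performance sections.

    Per source: AUC of that source's cases against its own controls.  Per
    stage: AUC of that stage's cases against ALL controls in the cohort,
    with the stage's score summary; early (0-II) and late (III-IV)
    composites are reported the same way.  Strata with fewer than 2 cases
    are skipped with a log entry.
    """
    samples = samples.set_index("sample_id").loc[scores.index]
    pos = samples["class"].to_numpy() == CANCER
    s = scores.to_numpy()
    control_scores = s[~pos]

    by_source = {}
    for source, grp in samples.groupby("source_id", sort=True):
        mask = samples.index.isin(grp.index)
        gpos = pos[mask]
        if gpos.sum() < 2 or (~gpos).sum() < 2:
            logger.info("source %s skipped (too few samples)", source)
            continue
        by_source[source] = {
            "auc": mannwhitney_auc(s[mask], gpos),
            "n_cancer": int(gpos.sum()), "n_control": int((~gpos).sum()),
        }

    def stage_block(stage_values: np.ndarray, name: str):
        case_scores = s[pos & stage_values]
        if len(case_scores) < 2:
            logger.info("stage stratum %s skipped (<2 cases)", name)
            return None
        merged = np.concatenate([case_scores, control_scores])
        labels = np.r_[np.ones(len(case_scores), bool),
                       np.zeros(len(control_scores), bool)]
        return {"auc": mannwhitney_auc(merged, labels),
                "n_cancer": int(len(case_scores)),
                "n_control": int(len(control_scores)),
                "scores": _score_summary(case_scores)}

    stage_arr = samples["stage"].to_numpy()
    by_stage = {}
    for stage in sorted(set(stage_arr) - {"not_applicable"}):
        block = stage_block(stage_arr == stage, stage)
        if block is not None:
            by_stage[stage] = block
    composites = {}
    early = stage_block(np.isin(stage_arr, EARLY_STAGES), "early(0-II)")
    late = stage_block(np.isin(stage_arr, LATE_STAGES), "late(III-IV)")
    if early is not None:
        composites["early_0_II"] = early
    if late is not None:
        composites["late_III_IV"] = late
    return {"by_source": by_source, "by_stage": by_stage,
            "stage_composites": composites,
            "control_scores": _score_summary(control_scores)}


def evaluate_cohort(model: PanelModel, norm_expr: pd.DataFrame,
                    samples: pd.DataFrame, cohort: str | None = None,
                    cutoff: float | None = None, seed: int = 0) -> dict:
    """Full evaluation report for one cohort.

    When ``cutoff`` is None the maximum-accuracy cutoff is derived on this
    cohort's scores (the operating point the study reports); passing the
    training cutoff evaluates the frozen rule instead.
    """
    if cohort is not None:
        samples = samples[samples["cohort"] == cohort]
    samples = samples[samples["sample_id"].isin(norm_expr.index)]
    expr = norm_expr.loc[samples["sample_id"]]
    scores = score_samples(model, expr)
    pos = samples["class"].to_numpy() == CANCER

    auc, auc_lo, auc_hi = auc_ci(scores.to_numpy(), pos, seed=seed)
    if cutoff is None:
        cutoff, _, _, _ = max_accuracy_cutoff(scores.to_numpy(), pos)
    pred = scores.to_numpy() >= cutoff
    tp = int((pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    n1, n0 = int(pos.sum()), int((~pos).sum())
    acc, acc_lo, acc_hi = proportion_ci(tp + tn, n1 + n0)
    sens, sens_lo, sens_hi = proportion_ci(tp, n1)
    spec, spec_lo, spec_hi = proportion_ci(tn, n0)

    report = {
        "cohort": cohort or "all",
        "n_cancer": n1, "n_control": n0,
        "auc": auc, "auc_ci": [auc_lo, auc_hi], "auc_ci_method": "delong",
        "cutoff": float(cutoff),
        "accuracy": acc, "accuracy_ci": [acc_lo, acc_hi],
        "sensitivity": sens, "sensitivity_ci": [sens_lo, sens_hi],
        "specificity": spec, "specificity_ci": [spec_lo, spec_hi],
        "proportion_ci_method": "wilson",
        "cancer_scores": _score_summary(scores.to_numpy()[pos]),
    }
    report.update(stratified_eval(scores, samples))
    return report
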