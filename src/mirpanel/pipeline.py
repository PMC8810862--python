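"""End-to-end orchestration: simulate -> quantify -> normalize -> differential
expression -> panel optimization -> held-out evaluation.

Reference miRNAs are selected on the discovery cohort only and applied
unchanged everywhere; candidate markers are selected on discovery and
confirmed on validation 1; panels are built on discovery + validation 1; the
validation 2 cohort is touched only by the final evaluation step, and a
leakage guard raises if any of its samples reach the panel stage.

:func:`run_study` executes the whole workflow in memory; :func:`run_pipeline`
wraps it with the on-disk artifact contract (TSV/JSON outputs, manifest,
run log) and is what the ``mirpanel run`` command calls.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, diffexpr, evaluate, io, normalize, panel, quantify
from .config import PipelineConfig
from .errors import CohortLeakageError, PipelineStageError
from .synth import TrueAbundanceMatrix, simulate_study

logger = logging.getLogger(__name__)


def assert_cohort_isolation(train_samples: pd.DataFrame) -> None:
    """Raise if any held-out (validation2) sample reaches a training stage."""
    leaked = train_samples.loc[train_samples["cohort"] == "validation2",
                               "sample_id"]
    if len(leaked):
        raise CohortLeakageError(
            f"validation2 samples leaked into panel stage: "
            f"{sorted(leaked)[:5]}")


def run_panel_stage(norm_expr: pd.DataFrame, train_samples: pd.DataFrame,
                    pool: list[str], config: PipelineConfig) -> tuple:
    """Cross-validated SFFS panel optimization on the training cohorts."""
    assert_cohort_isolation(train_samples)
    lo, hi = config.panel_sizes
    hi = min(hi, len(pool))
    if hi < lo:
        raise PipelineStageError(
            "panel", f"validated pool of {len(pool)} markers is smaller "
            f"than the minimum panel size {lo}")
    cv = panel.crossvalidate_panels(
        norm_expr.loc[train_samples["sample_id"]], train_samples, pool,
        n_iter=config.cv_iterations, sizes=range(lo, hi + 1),
        seed=config.seed)
    size = panel.optimal_size(cv, alpha=config.plateau_alpha)
    return cv, size


@dataclass
class StudyResult:
    """Everything the workflow computes, before any file is written."""

    config: PipelineConfig
    table: pd.DataFrame
    truth: TrueAbundanceMatrix
    ct: object
    expr: quantify.ExpressionMatrix
    stability: pd.DataFrame
    references: normalize.ReferenceSet
    norm_expr: pd.DataFrame
    norm_flags: pd.DataFrame
    stats_discovery: pd.DataFrame
    stats_validation1: pd.DataFrame
    candidates: diffexpr.CandidateSet
    fold_change_corr: dict | None
    cluster: dict | None
    cv: pd.DataFrame
    optimal_size: int
    model: panel.PanelModel
    report: dict
    log_lines: list[str] = field(default_factory=list)

    def cohort_frame(self, name: str):
        ids = [s for s in self.table.loc[self.table["cohort"] == name,
                                         "sample_id"]
               if s in self.norm_expr.index]
        labels = self.table.set_index("sample_id").loc[ids, "class"]
        return self.norm_expr.loc[ids], labels


def run_study(config: PipelineConfig) -> StudyResult:
    """Execute the full study workflow in memory."""
    config.validate()
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    stage = "simulate"
    try:
        table, truth, ct = simulate_study(config.simulate)
        log(f"simulate: {len(table)} samples, "
            f"{config.simulate.n_mirnas} miRNAs")

        stage = "quantify"
        expr = quantify.quantify_dataset(ct, table,
                                         config.simulate.spikein_copies)
        log(f"quantify: {expr.values.shape[0]} samples quantified, "
            f"{len(expr.excluded_samples)} excluded")

        stage = "normalize"
        disc = table[table["cohort"] == "discovery"]
        disc_ids = [s for s in disc["sample_id"] if s in expr.values.index]
        disc_expr = quantify.ExpressionMatrix(
            values=expr.values.loc[disc_ids],
            flags=expr.flags.loc[disc_ids])
        pool = normalize.candidate_pool(disc_expr)
        stab = normalize.stability_table(
            np.log2(disc_expr.values[pool]),
            disc.set_index("sample_id").loc[disc_ids, "class"])
        refs = normalize.select_references(stab, k=config.reference_k)
        norm_all = normalize.normalize_expression(expr, refs)
        log(f"normalize: references {refs.mirna_ids} "
            f"selected from {len(pool)} candidates on discovery")

        stage = "diffexpr"
        norm_expr = norm_all.values
        labels = table.set_index("sample_id")["class"]

        def cohort_xy(name):
            ids = [s for s in table.loc[table["cohort"] == name, "sample_id"]
                   if s in norm_expr.index]
            return norm_expr.loc[ids], labels.loc[ids]

        disc_x, disc_y = cohort_xy("discovery")
        val1_x, val1_y = cohort_xy("validation1")
        stats_disc = diffexpr.marker_stats(disc_x, disc_y)
        stats_val1 = diffexpr.marker_stats(val1_x, val1_y)
        discovery_pass = diffexpr.select_candidates(
            stats_disc, p_thresh=config.discovery_p,
            lfc_thresh=config.discovery_lfc, auc_thresh=config.discovery_auc,
            use_q=config.use_q)
        cand = diffexpr.validate_candidates(
            stats_val1, stats_disc, discovery_pass,
            p_thresh=config.validation_p, lfc_thresh=config.validation_lfc,
            use_q=config.use_q)
        corr = None
        if len(discovery_pass) >= 3:
            r, p = diffexpr.fold_change_correlation(stats_disc, stats_val1,
                                                    discovery_pass)
            corr = {"pearson_r": r, "p_value": p, "n": len(discovery_pass)}
        cluster = None
        if len(discovery_pass) >= 2:
            combined = pd.concat([disc_x, val1_x])[discovery_pass]
            s_order, m_order, _, _ = diffexpr.hierarchical_cluster(
                diffexpr.standardize_log2(combined))
            cluster = {"sample_order": s_order, "mirna_order": m_order}
        log(f"diffexpr: {len(discovery_pass)} discovery candidates, "
            f"{len(cand.validated)} validated")

        stage = "panel"
        train = table[table["cohort"].isin(["discovery", "validation1"])]
        train = train[train["sample_id"].isin(norm_expr.index)]
        cv, size = run_panel_stage(norm_expr, train, cand.validated, config)
        model = panel.select_final_panel(cv, size, disc_x, disc_y,
                                         val1_x, val1_y)
        train_scores = panel.score_samples(
            model, norm_expr.loc[train["sample_id"]])
        cut, _, _, _ = evaluate.max_accuracy_cutoff(
            train_scores.to_numpy(),
            labels.loc[train["sample_id"]].to_numpy() == "cancer")
        model.cutoff = cut
        model.metadata.update({"optimal_size": int(size),
                               "cv_iterations": config.cv_iterations,
                               "seed": config.seed})
        log(f"panel: optimal size {size}, final panel {model.mirna_ids}")

        stage = "evaluate"
        report = evaluate.evaluate_cohort(model, norm_expr, table,
                                          cohort="validation2",
                                          seed=config.seed)
        report["training_cutoff"] = float(cut)
        report["auc_discovery"] = diffexpr.mannwhitney_auc(
            panel.score_samples(model, disc_x).to_numpy(),
            disc_y.to_numpy() == "cancer")
        report["auc_validation1"] = diffexpr.mannwhitney_auc(
            panel.score_samples(model, val1_x).to_numpy(),
            val1_y.to_numpy() == "cancer")
        log(f"evaluate: validation2 AUC {report['auc']:.3f}")
    except (CohortLeakageError, PipelineStageError):
        raise
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    return StudyResult(
        config=config, table=table, truth=truth, ct=ct, expr=expr,
        stability=stab, references=refs, norm_expr=norm_expr,
        norm_flags=norm_all.flags, stats_discovery=stats_disc,
        stats_validation1=stats_val1, candidates=cand,
        fold_change_corr=corr, cluster=cluster, cv=cv,
        optimal_size=size, model=model, report=report,
        log_lines=log_lines)


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run the study and write every stage artifact; returns the run dir."""
    res = run_study(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    outputs: list[str] = []

    def emit(names: list[str]) -> None:
        outputs.extend(names)

    io.write_samples(res.table, out / "samples.tsv")
    io.write_ct_dataset(res.ct, out)
    io.write_truth(res.truth.truth, out / "truth.tsv")
    emit(["samples.tsv", "ct_long.tsv", "spikein_ct.tsv", "curve_ct.tsv",
          "truth.tsv"])

    io.write_expression(res.expr, out)
    emit(["expression.tsv", "flags.tsv"])

    res.stability.rename_axis("mirna_id").reset_index().to_csv(
        out / "stability.tsv", sep="\t", index=False)
    io.write_json({"mirna_ids": res.references.mirna_ids,
                   "selection_method": res.references.selection_method},
                  out / "references.json")
    io.write_expression(
        quantify.ExpressionMatrix(values=res.norm_expr,
                                  flags=res.norm_flags),
        out, name="normalized_expression.tsv")
    emit(["stability.tsv", "references.json", "normalized_expression.tsv"])

    for name, st in (("discovery", res.stats_discovery),
                     ("validation1", res.stats_validation1)):
        st.rename_axis("mirna_id").reset_index().to_csv(
            out / f"marker_stats_{name}.tsv", sep="\t", index=False)
    io.write_json({"discovery_pass": res.candidates.discovery_pass,
                   "validated": res.candidates.validated,
                   "excluded": res.candidates.excluded,
                   "fold_change_correlation": res.fold_change_corr},
                  out / "candidates.json")
    emit(["marker_stats_discovery.tsv", "marker_stats_validation1.tsv",
          "candidates.json"])
    if res.cluster is not None:
        io.write_json(res.cluster, out / "cluster_orders.json")
        emit(["cluster_orders.json"])

    res.cv.to_csv(out / "cv_records.tsv", sep="\t", index=False)
    io.write_json(res.model.to_dict(), out / "panel_model.json")
    emit(["cv_records.tsv", "panel_model.json"])

    io.write_json(res.report, out / "eval_report.json")
    val2 = res.table[res.table["cohort"] == "validation2"]
    val2 = val2[val2["sample_id"].isin(res.norm_expr.index)]
    scores_df = pd.DataFrame({
        "sample_id": val2["sample_id"].to_numpy(),
        "score": panel.score_samples(
            res.model, res.norm_expr.loc[val2["sample_id"]]).to_numpy(),
        "class": val2["class"].to_numpy(),
        "stage": val2["stage"].to_numpy(),
        "source_id": val2["source_id"].to_numpy(),
    })
    scores_df.to_csv(out / "scores.tsv", sep="\t", index=False)
    emit(["eval_report.json", "scores.tsv"])

    config_yaml = out / "config.yaml"
    config.to_yaml(config_yaml)
    cfg_hash = hashlib.sha256(config_yaml.read_bytes()).hexdigest()
    io.write_json({"package": "mirpanel", "version": __version__,
                   "seed": config.seed, "config_sha256": cfg_hash,
                   "outputs": outputs}, out / "manifest.json")
    (out / "run.log").write_text("\n".join(res.log_lines) + "\n",
                                 encoding="utf-8")
    return out
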