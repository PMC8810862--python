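"""Synthetic serum-miRNA cohort generator.

Generates case/control cohorts with the statistical and technical structure
the downstream analysis assumes: planted differential markers with known log2
fold changes, planted low-variance reference miRNAs, per-source batch shifts,
per-sample serum-content variation, RNA-isolation efficiency monitored by
three spike-in controls, per-assay standard curves (6-log serial dilution) and
Ct-level technical noise read out in duplicate.

Two substreams are derived from the configured seed — one for the cohort
(biology), one for the assay (technical) — so changing assay noise parameters
never perturbs the cohort draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (CURVE_LEVELS, NOT_APPLICABLE, RT_INPUT_FRACTION,
                     SERUM_VOLUME_ML, SPIKE_IDS, STAGES, SimulationConfig)
from .errors import GenerationError
from .quantify import CtDataset


@dataclass
class TrueAbundanceMatrix:
    """Ground-truth serum concentrations (copies/ml) plus marker annotations.

    ``values``: samples x miRNAs, strictly positive copies/ml.
    ``truth``: per-miRNA annotations (is_differential, true_log2fc,
    is_reference).
    """

    values: pd.DataFrame
    truth: pd.DataFrame

    def __post_init__(self):
        if (self.values.values <= 0).any():
            raise GenerationError("true abundances must be strictly positive")


def _substreams(config: SimulationConfig):
    cohort_ss, assay_ss = np.random.SeedSequence(config.seed).spawn(2)
    return np.random.default_rng(cohort_ss), np.random.default_rng(assay_ss)


def _mirna_ids(n: int) -> list[str]:
    return [f"miR-{i + 1:04d}" for i in range(n)]


def generate_cohort(config: SimulationConfig
                    ) -> tuple[pd.DataFrame, TrueAbundanceMatrix]:
    """Draw the sample table and the true abundance matrix.

    The log2 concentration of sample *i*, miRNA *m* is
    ``baseline_m + batch(source_i, m) + class_effect(m, i) + input_i + e_im``
    with ``e_im ~ N(0, bio_sd^2)`` (``ref_bio_sd`` for planted references) and
    ``input_i ~ N(0, input_variation_sd^2)`` shared by every miRNA of the
    sample (global serum miRNA content, which spike-ins cannot correct).
    """
    config.validate()
    rng, _ = _substreams(config)

    mirnas = _mirna_ids(config.n_mirnas)
    roles = rng.permutation(config.n_mirnas)
    diff_idx = roles[:config.n_differential]
    ref_idx = roles[config.n_differential:
                    config.n_differential + config.n_reference]

    true_lfc = np.zeros(config.n_mirnas)
    true_lfc[diff_idx] = config.log2fc_effects
    is_diff = np.zeros(config.n_mirnas, bool)
    is_diff[diff_idx] = True
    is_ref = np.zeros(config.n_mirnas, bool)
    is_ref[ref_idx] = True

    truth = pd.DataFrame({
        "mirna_id": mirnas,
        "is_differential": is_diff,
        "true_log2fc": true_lfc,
        "is_reference": is_ref,
    }).set_index("mirna_id")

    # Per-miRNA baseline abundance (log-normal across assays).
    baseline_log2 = rng.uniform(*config.baseline_log10_range,
                                config.n_mirnas) * np.log2(10.0)

    # Per source x miRNA batch shift.
    source_ids = sorted({s.source_id for s in config.sources})
    batch = {sid: rng.normal(0.0, config.batch_sd, config.n_mirnas)
             if config.batch_sd > 0 else np.zeros(config.n_mirnas)
             for sid in source_ids}

    stage_names = list(STAGES)
    stage_p = np.array([config.stage_probs[s] for s in stage_names])

    rows, log2_rows = [], []
    counter = 0
    for spec in config.sources:
        for cls, n in (("cancer", spec.n_cases),
                       ("non_cancer", spec.n_controls)):
            for _ in range(n):
                counter += 1
                sid = f"{spec.cohort}_{spec.source_id}_{cls[0]}{counter:04d}"
                if cls == "cancer":
                    stage = stage_names[rng.choice(len(stage_names),
                                                   p=stage_p)]
                    effect = true_lfc * config.stage_effect[stage]
                else:
                    stage = NOT_APPLICABLE
                    effect = 0.0
                age = float(np.clip(np.round(rng.normal(54.0, 8.0)), 26, 87))
                input_shift = (rng.normal(0.0, config.input_variation_sd)
                               if config.input_variation_sd > 0 else 0.0)
                noise_sd = np.where(is_ref, config.ref_bio_sd, config.bio_sd)
                subject_noise = rng.normal(0.0, 1.0, config.n_mirnas) * noise_sd
                log2_conc = (baseline_log2 + batch[spec.source_id] + effect
                             + input_shift + subject_noise)
                rows.append((sid, spec.cohort, spec.source_id, cls, stage, age))
                log2_rows.append(log2_conc)

    table = pd.DataFrame(rows, columns=["sample_id", "cohort", "source_id",
                                        "class", "stage", "age"])
    if table["sample_id"].duplicated().any():
        raise GenerationError("duplicate sample ids generated")
    values = pd.DataFrame(np.exp2(np.array(log2_rows)),
                          index=table["sample_id"].tolist(), columns=mirnas)
    values.index.name = "sample_id"
    return table, TrueAbundanceMatrix(values=values, truth=truth)


def simulate_assay(truth: TrueAbundanceMatrix, table: pd.DataFrame,
                   config: SimulationConfig) -> CtDataset:
    """Push true abundances through the measurement model to raw Ct values.

    Reacted copies = copies/ml x 0.2 ml serum x isolation efficiency x (2/25
    RT input fraction).  Observed Ct = slope * log10(reacted) + intercept +
    N(0, ct_sd^2), once per technical duplicate; reacted copies below one
    template are emitted as undetected (missing Ct).  Spike-in wells go
    through the same curve model with the sample's isolation efficiency (and
    no serum-volume term: spikes are added at lysis at known total copies).
    Standard-curve wells are generated at the six dilution levels.
    """
    config.validate()
    _, rng = _substreams(config)

    conc = truth.values
    if (conc.values <= 0).any():
        raise GenerationError("non-positive concentration in truth matrix")
    mirnas = list(conc.columns)
    samples = list(conc.index)
    if list(table["sample_id"]) != samples:
        conc = conc.loc[table["sample_id"]]
        samples = list(conc.index)

    assay_ids = mirnas + [f"spike_{s}" for s in SPIKE_IDS]
    slopes = rng.uniform(*config.curve_slope_range, len(assay_ids))
    intercepts = rng.uniform(*config.curve_intercept_range, len(assay_ids))
    slope_by = dict(zip(assay_ids, slopes))
    inter_by = dict(zip(assay_ids, intercepts))

    eff = rng.uniform(*config.isolation_eff_range, len(samples))

    n_s, n_m = conc.shape
    reacted = (conc.values * SERUM_VOLUME_ML * eff[:, None]
               * RT_INPUT_FRACTION)
    ct_clean = (slopes[None, :n_m] * np.log10(reacted)
                + intercepts[None, :n_m])
    detected = reacted >= 1.0

    dup = config.duplicate_count
    meas = []
    for rep in range(1, dup + 1):
        noise = (rng.normal(0.0, config.ct_sd, ct_clean.shape)
                 if config.ct_sd > 0 else 0.0)
        ct = np.where(detected, ct_clean + noise, np.nan)
        meas.append(pd.DataFrame({
            "sample_id": np.repeat(samples, n_m),
            "mirna_id": np.tile(mirnas, n_s),
            "replicate": rep,
            "ct": ct.ravel(),
        }))
    measurements = pd.concat(meas, ignore_index=True)

    spike_rows = []
    for j, sp in enumerate(SPIKE_IDS):
        aid = f"spike_{sp}"
        reacted_sp = (config.spikein_copies[sp] * eff * RT_INPUT_FRACTION)
        ct_sp = slope_by[aid] * np.log10(reacted_sp) + inter_by[aid]
        for rep in range(1, dup + 1):
            noise = (rng.normal(0.0, config.ct_sd, n_s)
                     if config.ct_sd > 0 else 0.0)
            spike_rows.append(pd.DataFrame({
                "sample_id": samples,
                "spike_id": sp,
                "replicate": rep,
                "ct": np.where(reacted_sp >= 1.0, ct_sp + noise, np.nan),
            }))
    spikein = pd.concat(spike_rows, ignore_index=True)

    levels = np.array(CURVE_LEVELS)
    curve_rows = []
    for aid in assay_ids:
        ct_lv = slope_by[aid] * np.log10(levels) + inter_by[aid]
        for rep in range(1, dup + 1):
            noise = (rng.normal(0.0, config.ct_sd, len(levels))
                     if config.ct_sd > 0 else 0.0)
            curve_rows.append(pd.DataFrame({
                "assay_id": aid,
                "input_copies": levels,
                "ct": ct_lv + noise,
            }))
    curve = pd.concat(curve_rows, ignore_index=True)

    return CtDataset(measurements=measurements, spikein_measurements=spikein,
                     curve_measurements=curve)


def simulate_study(config: SimulationConfig
                   ) -> tuple[pd.DataFrame, TrueAbundanceMatrix, CtDataset]:
    """Convenience wrapper: cohort draw followed by the assay simulation."""
    table, truth = generate_cohort(config)
    ct = simulate_assay(truth, table, config)
    return table, truth, ct
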