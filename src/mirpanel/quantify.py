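"""Absolute RT-qPCR quantification.

Converts raw Ct observations into copies per ml serum: per-assay standard
curves (ordinary least squares of Ct on log10 input copies) invert Ct to
reacted template copies; three spike-in controls of known input estimate each
sample's RNA-isolation recovery; volume bookkeeping (0.2 ml serum, 2/25 RT
input fraction) rescales reacted copies to the serum concentration.

Quantifying every assay against its own curve is what correcting for
per-assay RT-qPCR efficiency operationally means; no second correction is
applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RT_INPUT_FRACTION, SERUM_VOLUME_ML, SPIKE_IDS
from .errors import (ConfigurationError, DegenerateCurveError,
                     InvalidAssayError, SampleQualityError)

logger = logging.getLogger(__name__)

FLAG_INTERPOLATED = "interpolated"
FLAG_EXTRAP_LOW = "extrapolated_low"
FLAG_EXTRAP_HIGH = "extrapolated_high"
FLAG_FLOORED = "floored"
FLAG_MISSING = "missing"

#: duplicates further apart than this many cycles are flagged as discordant
DISCORDANT_CT_DELTA = 2.0


@dataclass
class CtDataset:
    """Raw qPCR observations in long format.

    ``measurements``: sample_id, mirna_id, replicate, ct (NaN = undetected).
    ``spikein_measurements``: sample_id, spike_id, replicate, ct.
    ``curve_measurements``: assay_id, input_copies, ct.
    ``ntc``: optional non-template-control wells (assay_id, ct).
    """

    measurements: pd.DataFrame
    spikein_measurements: pd.DataFrame
    curve_measurements: pd.DataFrame
    ntc: pd.DataFrame | None = None


@dataclass(frozen=True)
class StandardCurve:
    """Linear Ct-vs-log10(copies) model for one assay."""

    assay_id: str
    slope: float        # cycles per log10(copies), < 0
    intercept: float    # cycles at 1 copy
    r_squared: float
    efficiency: float   # 10^(-1/slope) - 1; 1.0 = perfect doubling
    level_range: tuple[float, float]


@dataclass
class ExpressionMatrix:
    """Samples x miRNAs absolute abundances (copies/ml serum) with flags."""

    values: pd.DataFrame
    flags: pd.DataFrame
    excluded_samples: dict[str, str] = field(default_factory=dict)


def fit_standard_curve(points, assay_id: str = "assay") -> StandardCurve:
    """OLS fit of Ct on log10(input copies).

    ``points``: iterable of (input_copies, ct) with at least two distinct
    copy levels, all copies > 0.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise DegenerateCurveError(
            f"{assay_id}: need >= 2 (copies, ct) points")
    copies, ct = pts[:, 0], pts[:, 1]
    if (copies <= 0).any():
        raise DegenerateCurveError(f"{assay_id}: input copies must be > 0")
    x = np.log10(copies)
    if np.unique(x).size < 2:
        raise DegenerateCurveError(
            f"{assay_id}: fewer than 2 distinct input levels")
    res = stats.linregress(x, ct)
    if res.slope >= 0:
        raise InvalidAssayError(
            f"{assay_id}: fitted slope {res.slope:.4f} is not negative")
    return StandardCurve(
        assay_id=assay_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        efficiency=float(10.0 ** (-1.0 / res.slope) - 1.0),
        level_range=(float(copies.min()), float(copies.max())),
    )


def fit_all_curves(curve_measurements: pd.DataFrame
                   ) -> dict[str, StandardCurve]:
    """Fit one standard curve per assay from long-format curve wells."""
    return {
        str(aid): fit_standard_curve(
            grp[["input_copies", "ct"]].to_numpy(), assay_id=str(aid))
        for aid, grp in curve_measurements.groupby("assay_id", sort=True)
    }


def ct_to_copies(ct: float, curve: StandardCurve) -> tuple[float, str]:
    """Invert the standard curve: copies = 10^((ct - intercept) / slope).

    Returns the copy number and a provenance flag (interpolated within the
    curve's dilution range, else extrapolated_low / extrapolated_high).
    """
    copies = 10.0 ** ((ct - curve.intercept) / curve.slope)
    lo, hi = curve.level_range
    # relative tolerance so cells at exactly a dilution level interpolate
    if copies < lo * (1.0 - 1e-9):
        flag = FLAG_EXTRAP_LOW
    elif copies > hi * (1.0 + 1e-9):
        flag = FLAG_EXTRAP_HIGH
    else:
        flag = FLAG_INTERPOLATED
    return copies, flag


def spikein_recovery(sample_spike_cts: pd.DataFrame,
                     spike_curves: dict[str, StandardCurve],
                     expected_copies: dict[str, float]) -> float:
    """Per-sample RNA-isolation recovery from the spike-in controls.

    Technical duplicates are averaged on the Ct scale, each spike's measured
    copies are read off its own curve, and the recovery is the geometric mean
    of measured/expected over the observed spikes.  ``expected_copies`` are on
    the reacted (RT input) scale.
    """
    ratios = []
    for spike_id, grp in sample_spike_cts.groupby("spike_id", sort=True):
        cts = grp["ct"].dropna()
        if cts.empty:
            continue
        measured, _ = ct_to_copies(float(cts.mean()), spike_curves[spike_id])
        ratios.append(measured / expected_copies[spike_id])
    if not ratios:
        raise SampleQualityError("all spike-ins undetected")
    return float(np.exp(np.mean(np.log(ratios))))


def compute_recoveries(ct_data: CtDataset,
                       curves: dict[str, StandardCurve],
                       spikein_copies: dict[str, float],
                       rt_fraction: float = RT_INPUT_FRACTION
                       ) -> tuple[pd.Series, dict[str, str]]:
    """Recovery per sample; failed samples returned separately with reasons."""
    expected = {sp: spikein_copies[sp] * rt_fraction for sp in SPIKE_IDS}
    spike_curves = {sp: curves[f"spike_{sp}"] for sp in SPIKE_IDS}
    recov, failed = {}, {}
    for sid, grp in ct_data.spikein_measurements.groupby("sample_id",
                                                         sort=True):
        try:
            recov[sid] = spikein_recovery(grp, spike_curves, expected)
        except SampleQualityError as exc:
            failed[sid] = str(exc)
            logger.warning("sample %s excluded: %s", sid, exc)
    return pd.Series(recov, name="recovery"), failed


def absolute_quantify(ct_data: CtDataset,
                      curves: dict[str, StandardCurve],
                      sample_table: pd.DataFrame,
                      spikein_copies: dict[str, float],
                      rt_fraction: float = RT_INPUT_FRACTION,
                      serum_volume_ml: float = SERUM_VOLUME_ML
                      ) -> ExpressionMatrix:
    """Quantify every sample x miRNA cell as copies per ml serum.

    Per cell: average technical duplicates on the Ct scale, invert the
    assay's standard curve, divide by the sample's spike-in recovery, the RT
    input fraction and the serum volume.  Cells undetected in every duplicate
    are set to the detection floor (the lowest curve level rescaled the same
    way) and flagged ``floored``.  Samples whose spike-ins all failed are
    excluded with a log entry.
    """
    mirnas = sorted(ct_data.measurements["mirna_id"].unique())
    missing = [m for m in mirnas if m not in curves]
    if missing:
        raise ConfigurationError(
            f"no standard curve for assays: {missing[:5]}")

    recovery, failed = compute_recoveries(ct_data, curves, spikein_copies,
                                          rt_fraction)
    samples = [s for s in sample_table["sample_id"] if s not in failed]

    # mean Ct and detected-duplicate count per cell, vectorized
    meas = ct_data.measurements
    mean_ct = (meas.pivot_table(index="sample_id", columns="mirna_id",
                                values="ct", aggfunc="mean")
               .reindex(index=samples, columns=mirnas))
    n_det = (meas.assign(det=meas["ct"].notna())
             .pivot_table(index="sample_id", columns="mirna_id",
                          values="det", aggfunc="sum")
             .reindex(index=samples, columns=mirnas)
             .fillna(0))
    ct_max = meas.pivot_table(index="sample_id", columns="mirna_id",
                              values="ct", aggfunc="max")
    ct_min = meas.pivot_table(index="sample_id", columns="mirna_id",
                              values="ct", aggfunc="min")
    ct_spread = (ct_max - ct_min).reindex(index=samples, columns=mirnas)
    n_discordant = int((ct_spread > DISCORDANT_CT_DELTA).sum().sum())
    if n_discordant:
        logger.warning("%d cells with discordant duplicates (|dCt| > %.1f); "
                       "averaged anyway", n_discordant, DISCORDANT_CT_DELTA)

    slopes = np.array([curves[m].slope for m in mirnas])
    inters = np.array([curves[m].intercept for m in mirnas])
    lo = np.array([curves[m].level_range[0] for m in mirnas])
    hi = np.array([curves[m].level_range[1] for m in mirnas])

    reacted = 10.0 ** ((mean_ct.values - inters[None, :]) / slopes[None, :])
    scale = (recovery.reindex(samples).values[:, None]
             * rt_fraction * serum_volume_ml)
    values = reacted / scale

    flags = np.full(values.shape, FLAG_INTERPOLATED, dtype=object)
    flags[reacted < lo[None, :] * (1.0 - 1e-9)] = FLAG_EXTRAP_LOW
    flags[reacted > hi[None, :] * (1.0 + 1e-9)] = FLAG_EXTRAP_HIGH
    undet = n_det.values == 0
    values[undet] = (np.broadcast_to(lo[None, :], values.shape) / scale)[undet]
    flags[undet] = FLAG_FLOORED

    values_df = pd.DataFrame(values, index=samples, columns=mirnas)
    values_df.index.name = "sample_id"
    flags_df = pd.DataFrame(flags, index=samples, columns=mirnas)
    flags_df.index.name = "sample_id"
    return ExpressionMatrix(values=values_df, flags=flags_df,
                            excluded_samples=failed)


def quantify_dataset(ct_data: CtDataset, sample_table: pd.DataFrame,
                     spikein_copies: dict[str, float]) -> ExpressionMatrix:
    """Fit all curves then quantify; the common entry point."""
    curves = fit_all_curves(ct_data.curve_measurements)
    return absolute_quantify(ct_data, curves, sample_table, spikein_copies)
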