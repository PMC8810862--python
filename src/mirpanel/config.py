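"""Simulation and pipeline configuration.

The default :class:`SimulationConfig` reproduces the structure of the study the
pipeline is built for: 324 assayed serum miRNAs, ~30 truly differential markers
with |log2FC| >= 0.5, 3 planted stable reference miRNAs, three phases
(discovery / validation1 / validation2) drawn from six sample sources, RNA
isolation monitored by three spike-in controls, and 6-log standard curves
(10^7 down to 10^2 template copies) read out in technical duplicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .errors import ConfigurationError

COHORTS = ("discovery", "validation1", "validation2")
STAGES = ("0", "I", "II", "III", "IV", "unknown")
NOT_APPLICABLE = "not_applicable"
SPIKE_IDS = ("high", "medium", "low")

#: Protocol volume bookkeeping: 200 ul serum in, RNA eluted in 25 ul,
#: 2 ul of eluate per RT reaction.
SERUM_VOLUME_ML = 0.2
ELUATE_VOLUME_UL = 25.0
RT_INPUT_UL = 2.0
RT_INPUT_FRACTION = RT_INPUT_UL / ELUATE_VOLUME_UL

#: Standard-curve serial dilution: 10 million down to 100 copies (6 logs).
CURVE_LEVELS = tuple(10.0 ** k for k in range(7, 1, -1))


@dataclass(frozen=True)
class SourceSpec:
    """One sample source within one study phase."""

    source_id: str
    cohort: str
    n_cases: int
    n_controls: int

    def validate(self) -> None:
        if self.cohort not in COHORTS:
            raise ConfigurationError(f"sources: unknown cohort {self.cohort!r}")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigurationError("sources: negative sample count")


def table1_sources() -> tuple[SourceSpec, ...]:
    """The six-source, three-phase cohort layout used by default.

    Discovery: one Caucasian source (183 cancer / 106 non-cancer).
    Validation 1 and 2: five mixed Caucasian/Asian sources.
    """
    return (
        SourceSpec("source1", "discovery", 183, 106),
        SourceSpec("source2", "validation1", 39, 39),
        SourceSpec("source3", "validation1", 23, 33),
        SourceSpec("source4", "validation1", 48, 47),
        SourceSpec("source5", "validation1", 38, 35),
        SourceSpec("source6", "validation1", 29, 43),
        SourceSpec("source2", "validation2", 40, 39),
        SourceSpec("source3", "validation2", 24, 34),
        SourceSpec("source4", "validation2", 48, 47),
        SourceSpec("source5", "validation2", 38, 35),
        SourceSpec("source6", "validation2", 30, 44),
    )


def default_effects(n_differential: int = 30,
                    min_abs: float = 0.5,
                    max_abs: float = 1.5) -> np.ndarray:
    """Signed log2 fold-change effects for the planted differential markers.

    Magnitudes are evenly spaced in [min_abs, max_abs]; signs alternate so the
    panel contains both up- and down-regulated markers.
    """
    if n_differential == 0:
        return np.array([])
    mags = np.linspace(max_abs, min_abs, n_differential)
    signs = np.where(np.arange(n_differential) % 2 == 0, 1.0, -1.0)
    return mags * signs


def _default_stage_probs() -> dict[str, float]:
    # Pooled case stage distribution across the three phases.
    return {"0": 0.072, "I": 0.320, "II": 0.365,
            "III": 0.076, "IV": 0.011, "unknown": 0.156}


def _default_stage_effect() -> dict[str, float]:
    return {s: 1.0 for s in STAGES}


def _default_spikein_copies() -> dict[str, float]:
    # High / medium / low RNA spike-in inputs (copies added per sample).
    return {"high": 2e5, "medium": 2e4, "low": 2e3}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-cohort generator.

    Noise parameters are on the scales the instrument and biology produce
    them: ``bio_sd``, ``batch_sd``, ``input_variation_sd`` in log2 units,
    ``ct_sd`` in PCR cycles.
    """

    n_mirnas: int = 324
    n_differential: int = 30
    log2fc_effects: np.ndarray | None = None
    n_reference: int = 3
    sources: tuple[SourceSpec, ...] = field(default_factory=table1_sources)
    batch_sd: float = 0.25          # per source x miRNA shift, log2
    bio_sd: float = 1.0             # between-subject, log2
    ref_bio_sd: float = 0.15        # between-subject for planted references
    input_variation_sd: float = 0.3  # per-sample global serum content, log2
    ct_sd: float = 0.25             # technical Ct noise, cycles
    duplicate_count: int = 2
    isolation_eff_range: tuple[float, float] = (0.5, 1.0)
    spikein_copies: dict[str, float] = field(default_factory=_default_spikein_copies)
    curve_slope_range: tuple[float, float] = (-3.6, -3.2)
    curve_intercept_range: tuple[float, float] = (37.0, 40.0)
    baseline_log10_range: tuple[float, float] = (4.5, 7.5)  # copies/ml serum
    stage_probs: dict[str, float] = field(default_factory=_default_stage_probs)
    stage_effect: dict[str, float] = field(default_factory=_default_stage_effect)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.log2fc_effects is None:
            self.log2fc_effects = default_effects(self.n_differential)
        self.log2fc_effects = np.asarray(self.log2fc_effects, dtype=float)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_mirnas < 1:
            raise ConfigurationError("n_mirnas must be >= 1")
        if self.n_differential + self.n_reference > self.n_mirnas:
            raise ConfigurationError(
                "n_differential + n_reference exceeds n_mirnas")
        if len(self.log2fc_effects) != self.n_differential:
            raise ConfigurationError(
                "log2fc_effects length must equal n_differential")
        for name in ("batch_sd", "bio_sd", "ref_bio_sd",
                     "input_variation_sd", "ct_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.duplicate_count < 1:
            raise ConfigurationError("duplicate_count must be >= 1")
        lo, hi = self.isolation_eff_range
        if not (0 < lo <= hi <= 1):
            raise ConfigurationError(
                "isolation_eff_range must satisfy 0 < low <= high <= 1")
        if self.curve_slope_range[0] > self.curve_slope_range[1]:
            raise ConfigurationError("curve_slope_range out of order")
        if self.curve_slope_range[1] >= 0:
            raise ConfigurationError("curve_slope_range: slopes must be < 0")
        if set(self.spikein_copies) != set(SPIKE_IDS):
            raise ConfigurationError(
                f"spikein_copies must have keys {SPIKE_IDS}")
        if any(v <= 0 for v in self.spikein_copies.values()):
            raise ConfigurationError("spikein_copies must be > 0")
        if set(self.stage_probs) != set(STAGES):
            raise ConfigurationError(f"stage_probs must have keys {STAGES}")
        if abs(sum(self.stage_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("stage_probs must sum to 1")
        if not self.sources:
            raise ConfigurationError("sources must be non-empty")
        for s in self.sources:
            s.validate()
        if not (0 <= self.seed < 2 ** 31):
            raise ConfigurationError("seed must be in [0, 2^31)")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["log2fc_effects"] = [float(x) for x in self.log2fc_effects]
        d["sources"] = [list(asdict(s).values()) for s in self.sources]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "sources" in d:
            d["sources"] = tuple(SourceSpec(*s) for s in d["sources"])
        if d.get("log2fc_effects") is not None:
            d["log2fc_effects"] = np.asarray(d["log2fc_effects"], dtype=float)
        for key in ("isolation_eff_range", "curve_slope_range",
                    "curve_intercept_range", "baseline_log10_range"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class PipelineConfig:
    """End-to-end run configuration; defaults mirror the study's parameters."""

    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    reference_k: int = 3
    discovery_p: float = 0.01
    discovery_lfc: float = 0.5
    discovery_auc: float = 0.5
    validation_p: float = 0.05
    validation_lfc: float = 0.5
    use_q: bool = False
    cv_iterations: int = 200
    panel_sizes: tuple[int, int] = (2, 12)
    plateau_alpha: float = 0.001
    seed: int = 0

    def validate(self) -> None:
        self.simulate.validate()
        if self.reference_k < 1:
            raise ConfigurationError("reference_k must be >= 1")
        for name in ("discovery_p", "validation_p", "plateau_alpha"):
            if not (0 < getattr(self, name) <= 1):
                raise ConfigurationError(f"{name} must be in (0, 1]")
        lo, hi = self.panel_sizes
        if not (1 <= lo <= hi):
            raise ConfigurationError("panel_sizes out of order")
        if self.cv_iterations < 1:
            raise ConfigurationError("cv_iterations must be >= 1")
        if not (0 <= self.seed < 2 ** 31):
            raise ConfigurationError("seed must be in [0, 2^31)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulate"] = self.simulate.to_dict()
        d["panel_sizes"] = list(self.panel_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulate" in d:
            d["simulate"] = SimulationConfig.from_dict(d["simulate"])
        if "panel_sizes" in d:
            d["panel_sizes"] = tuple(d["panel_sizes"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
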