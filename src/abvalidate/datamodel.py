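"""Core domain types for Western-blot antibody validation.

The vocabulary follows common usage in antibody characterisation work:

* an :class:`AbundancePanel` holds an antibody-independent quantification of
  genes across a sample panel (RNA-seq TPM, targeted-MS ratio-to-standard,
  or TMT median intensity), or antibody-derived band intensities;
* a :class:`LaneProfile` is what densitometry extracts from one blot lane —
  the detected bands with apparent molecular weights and intensities;
* a :class:`PillarResult` scores one of the five validation strategies
  ("pillars") for one antibody, and a :class:`ValidationReport` aggregates
  the per-pillar statuses into the enhanced/uncertain/not-done summary.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .errors import DataValueError, DuplicateKeyError, ParameterError, UsageError

__all__ = [
    "SampleKind",
    "MeasurementKind",
    "Sample",
    "AbundancePanel",
    "Band",
    "LaneProfile",
    "AntibodyRecord",
    "PillarConfig",
    "Pillar",
    "PillarStatus",
    "PillarResult",
    "ValidationReport",
]


class SampleKind(str, Enum):
    CELL_LINE = "cell_line"
    TISSUE = "tissue"
    PLASMA = "plasma"


class MeasurementKind(str, Enum):
    """What the numbers in an abundance panel mean."""

    TPM = "tpm"                      # RNA-seq transcripts per million
    PRM_RATIO = "prm_ratio"          # targeted MS, light/heavy ratio to spiked standard
    TMT_INTENSITY = "tmt_intensity"  # isobaric-label median protein intensity
    BAND_INTENSITY = "band_intensity"  # densitometry of Western-blot bands


@dataclass(frozen=True)
class Sample:
    sample_id: str
    kind: SampleKind = SampleKind.CELL_LINE

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise DataValueError("sample_id must be nonempty")


@dataclass
class AbundancePanel:
    """Genes x samples quantification matrix with an explicit measurement kind.

    ``values`` is nonnegative; NaN marks a missing measurement (dropped
    pairwise by downstream correlation). ``replicate_sd`` optionally carries
    the across-replicate standard deviation, same shape.
    """

    measurement_kind: MeasurementKind
    genes: list[str]
    samples: list[Sample]
    values: np.ndarray
    replicate_sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.measurement_kind = MeasurementKind(self.measurement_kind)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise DataValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise DuplicateKeyError(f"duplicate gene identifiers: {dupes}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise DuplicateKeyError("duplicate sample ids in panel")
        if np.any(self.values[~np.isnan(self.values)] < 0):
            r, c = np.argwhere(np.nan_to_num(self.values, nan=0.0) < 0)[0]
            raise DataValueError(
                f"negative value at gene {self.genes[r]!r}, sample {ids[c]!r}"
            )
        if self.replicate_sd is not None:
            self.replicate_sd = np.asarray(self.replicate_sd, dtype=float)
            if self.replicate_sd.shape != self.values.shape:
                raise DataValueError("replicate_sd shape differs from values")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def series(self, gene: str) -> np.ndarray:
        """Row vector of abundances for one gene (copy)."""
        try:
            i = self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in panel") from None
        return self.values[i].copy()


@dataclass(frozen=True)
class Band:
    """One stained band: apparent molecular weight (kDa) and densitometry intensity."""

    apparent_mw_kda: float
    intensity: float

    def __post_init__(self) -> None:
        if not (self.apparent_mw_kda > 0):
            raise DataValueError(f"apparent_mw_kda must be > 0, got {self.apparent_mw_kda}")
        if self.intensity < 0 or math.isnan(self.intensity):
            raise DataValueError(f"intensity must be >= 0, got {self.intensity}")


@dataclass
class LaneProfile:
    """All bands one antibody stains in one sample's lane.

    Bands are kept sorted by descending apparent MW (top of gel first).
    """

    antibody_id: str
    sample_id: str
    bands: list[Band] = field(default_factory=list)
    loading_control_intensity: Optional[float] = None

    def __post_init__(self) -> None:
        self.bands = sorted(self.bands, key=lambda b: -b.apparent_mw_kda)
        if self.loading_control_intensity is not None and not (
            self.loading_control_intensity > 0
        ):
            raise DataValueError("loading_control_intensity must be positive when given")


@dataclass(frozen=True)
class AntibodyRecord:
    """Metadata for one antibody: its target gene and (optionally) the epitope
    interval on the target protein, 1-based inclusive amino-acid coordinates."""

    antibody_id: str
    target_gene: str
    epitope_interval: Optional[tuple[int, int]] = None
    application: str = "western_blot"

    def __post_init__(self) -> None:
        if self.epitope_interval is not None:
            s, e = self.epitope_interval
            if s > e:
                raise DataValueError(f"epitope start {s} > end {e}")


@dataclass
class PillarConfig:
    """All tunable decision thresholds, in one place.

    r_min
        Pearson correlation an antibody's band series must exceed (strictly)
        against the orthogonal series. Default 0.5.
    fold_min
        Minimum max/min fold-change the orthogonal series must reach for a
        correlation to be interpretable; below it the pillar is ``uncertain``.
        Default 5.
    kd_min_fraction
        Fraction of target-band signal that must disappear (strictly more)
        after siRNA knockdown. Default 0.25.
    dominance_ratio
        How much stronger the dominant band must be than the runner-up to be
        "clearly separated". Default 2x.
    mw_gap_log10
        Minimum |log10 MW| gap between the dominant band and its nearest
        neighbour for clear separation. Default 0.05 (~12% MW difference).
    mw_tolerance_slices
        Capture-MS: bands within this many gel slices of the modal slice are
        concordant; within twice it, "just outside" -> uncertain. Default 1.
    mw_match_log10
        Independent-antibody / recombinant pillars: two bands are "the same"
        when their log10 MWs differ by at most this. Default 0.1, about one
        ladder interval on a standard prestained ladder.
    oe_min_ratio
        Recombinant expression: overexpressed band must be at least this many
        times the matched control band. Default 5.
    pseudocount
        Added to values before ratios/logs to tame zeros. Default 0.1.
    log_transform
        Correlate on log2(value + pseudocount) instead of linear values.
        Default False.
    """

    r_min: float = 0.5
    fold_min: float = 5.0
    kd_min_fraction: float = 0.25
    dominance_ratio: float = 2.0
    mw_tolerance_slices: int = 1
    mw_gap_log10: float = 0.05
    mw_match_log10: float = 0.1
    oe_min_ratio: float = 5.0
    pseudocount: float = 0.1
    log_transform: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.r_min < 1):
            raise ParameterError(f"r_min must be in (0,1), got {self.r_min}")
        if not (self.fold_min > 1):
            raise ParameterError(f"fold_min must be > 1, got {self.fold_min}")
        if not (0 < self.kd_min_fraction < 1):
            raise ParameterError(
                f"kd_min_fraction must be in (0,1), got {self.kd_min_fraction}"
            )
        if self.pseudocount < 0:
            raise ParameterError(f"pseudocount must be >= 0, got {self.pseudocount}")
        if self.dominance_ratio < 1:
            raise ParameterError("dominance_ratio must be >= 1")
        if self.mw_tolerance_slices < 0:
            raise ParameterError("mw_tolerance_slices must be >= 0")
        if self.oe_min_ratio <= 1:
            raise ParameterError("oe_min_ratio must be > 1")


class Pillar(str, Enum):
    ORTHOGONAL = "orthogonal"
    CAPTURE_MS = "capture_ms"
    INDEPENDENT = "independent"
    GENETIC = "genetic"
    RECOMBINANT = "recombinant"


class PillarStatus(str, Enum):
    ENHANCED = "enhanced"
    NOT_VALIDATED = "not_validated"
    UNCERTAIN = "uncertain"
    NOT_DONE = "not_done"


@dataclass
class PillarResult:
    pillar: Pillar
    status: PillarStatus
    metrics: dict[str, float] = field(default_factory=dict)
    note: str = ""

    def __post_init__(self) -> None:
        self.pillar = Pillar(self.pillar)
        self.status = PillarStatus(self.status)


@dataclass
class ValidationReport:
    """Per-antibody aggregation over the five pillars; every pillar has exactly
    one slot, missing attempts filled with ``not_done``."""

    antibody_id: str
    pillar_results: list[PillarResult]
    n_enhanced: int = -1

    def __post_init__(self) -> None:
        pillars = [r.pillar for r in self.pillar_results]
        if len(set(pillars)) != len(pillars):
            raise UsageError("duplicate pillar in report")
        n = sum(1 for r in self.pillar_results if r.status is PillarStatus.ENHANCED)
        if self.n_enhanced == -1:
            self.n_enhanced = n
        elif self.n_enhanced != n:
            raise DataValueError(
                f"n_enhanced={self.n_enhanced} but {n} pillars are enhanced"
            )

    def status_of(self, pillar: Pillar) -> PillarStatus:
        for r in self.pillar_results:
            if r.pillar is Pillar(pillar):
                return r.status
        return PillarStatus.NOT_DONE
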