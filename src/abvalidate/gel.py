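"""SDS-PAGE physics surrogate.

Everything about molecular weight lives here: ladder calibration (migration is
linear in log10 MW between knots, the standard reading of an SDS-PAGE gel),
theoretical MW from sequence (average residue masses, no PTMs), dominant-band
analysis, and the capture-MS "virtual Western" — reconstructing a protein's
migration profile from per-gel-slice peptide identifications and asking whether
the antibody's band sits where the peptides do.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .datamodel import Band, LaneProfile, Pillar, PillarConfig, PillarResult, PillarStatus
from .errors import (
    CalibrationError,
    DataValueError,
    EmptyLaneError,
    GelRangeError,
    ProteinNotCoveredError,
    SequenceError,
)

__all__ = [
    "AVERAGE_RESIDUE_MASS_DA",
    "WATER_MASS_DA",
    "theoretical_mw",
    "LadderCalibration",
    "calibrate_ladder",
    "apparent_mw",
    "mw_histogram",
    "dominant_band",
    "SliceSet",
    "make_slice_grid",
    "VirtualWestern",
    "build_virtual_western",
    "capture_ms_match",
    "CROWDED_MW_RANGE_KDA",
]

# Average (not monoisotopic) residue masses in daltons — residue = amino acid
# minus water, so a chain's mass is sum(residues) + one water.
AVERAGE_RESIDUE_MASS_DA: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS_DA = 18.0153

# Gel region where many unrelated proteins co-migrate; capture-MS concordance
# there warrants extra caution and is flagged in the pillar metrics.
CROWDED_MW_RANGE_KDA = (30.0, 70.0)


def theoretical_mw(sequence: str) -> float:
    """Average molecular weight of an unmodified protein chain, in kDa.

    Sum of average residue masses plus one water; raises
    :class:`SequenceError` on empty input or non-standard letters.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise SequenceError("empty sequence")
    total = WATER_MASS_DA
    for i, aa in enumerate(seq):
        try:
            total += AVERAGE_RESIDUE_MASS_DA[aa]
        except KeyError:
            raise SequenceError(f"unknown amino acid {aa!r} at position {i + 1}") from None
    return total / 1000.0


@dataclass(frozen=True)
class LadderCalibration:
    """Piecewise log-linear map from migration distance to apparent MW.

    ``migrations`` strictly increasing, ``mws_kda`` strictly decreasing —
    smaller proteins run further.
    """

    migrations: tuple[float, ...]
    mws_kda: tuple[float, ...]

    def apparent_mw(self, migration: float, allow_extrapolation: bool = False) -> float:
        return apparent_mw(self, migration, allow_extrapolation=allow_extrapolation)

    @property
    def migration_range(self) -> tuple[float, float]:
        return self.migrations[0], self.migrations[-1]


def calibrate_ladder(points: Iterable[tuple[float, float]]) -> LadderCalibration:
    """Build a calibration from ladder knots (migration, MW in kDa)."""
    pts = sorted((float(m), float(w)) for m, w in points)
    if len(pts) < 2:
        raise CalibrationError(f"need >= 2 ladder points, got {len(pts)}")
    migs = [p[0] for p in pts]
    mws = [p[1] for p in pts]
    if any(not (w > 0) for w in mws) or any(not (m > 0) for m in migs):
        raise CalibrationError("migrations and MWs must be positive")
    if any(b <= a for a, b in zip(migs, migs[1:])):
        raise CalibrationError("ladder migrations must be strictly increasing")
    if any(b >= a for a, b in zip(mws, mws[1:])):
        raise CalibrationError("ladder MWs must be strictly decreasing with migration")
    return LadderCalibration(tuple(migs), tuple(mws))


def apparent_mw(
    calibration: LadderCalibration, migration: float, allow_extrapolation: bool = False
) -> float:
    """Apparent MW (kDa) at a migration distance, log10-linear between knots."""
    migs = np.asarray(calibration.migrations)
    logw = np.log10(calibration.mws_kda)
    if migration < migs[0] or migration > migs[-1]:
        if not allow_extrapolation:
            raise GelRangeError(
                f"migration {migration} outside calibrated range "
                f"[{migs[0]}, {migs[-1]}]"
            )
        # continue the end segment's slope
        if migration < migs[0]:
            slope = (logw[1] - logw[0]) / (migs[1] - migs[0])
            return float(10 ** (logw[0] + slope * (migration - migs[0])))
        slope = (logw[-1] - logw[-2]) / (migs[-1] - migs[-2])
        return float(10 ** (logw[-1] + slope * (migration - migs[-1])))
    return float(10 ** np.interp(migration, migs, logw))


def mw_histogram(
    mws: Sequence[float],
    labels: Optional[Sequence[str]] = None,
    n_bins: int = 30,
) -> dict:
    """Histogram of molecular weights on a log2 axis.

    Returns ``{"edges_log2": ..., "counts": ..., "per_class": {label: counts}}``;
    counts conserve the total number of proteins, and per-class counts sum to
    the overall counts. Used for proteome-wide MW distributions (most human
    proteins cluster near 50 kDa, ~450 residues).
    """
    arr = np.asarray(mws, dtype=float)
    if arr.size and np.any(arr <= 0):
        raise DataValueError("all molecular weights must be positive")
    if labels is not None and len(labels) != arr.size:
        raise DataValueError("labels length must match mws length")
    log2 = np.log2(arr) if arr.size else arr
    if arr.size:
        edges = np.histogram_bin_edges(log2, bins=n_bins)
    else:
        edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(log2, bins=edges)
    out = {"edges_log2": edges, "counts": counts, "per_class": {}}
    if labels is not None:
        lab = np.asarray(labels)
        for cls in sorted(set(labels)):
            c, _ = np.histogram(log2[lab == cls], bins=edges)
            out["per_class"][cls] = c
    return out


def dominant_band(lane: LaneProfile, config: PillarConfig) -> tuple[Band, bool]:
    """The strongest-stained band and whether it is clearly separated.

    Only the strongest band in a lane is eligible for validation, and only
    when it stands clear of the weaker bands: at least ``dominance_ratio``
    times the runner-up intensity AND at least ``mw_gap_log10`` away from the
    nearest other band in log10 MW. A single band is trivially separated; an
    exact intensity tie is never separated.
    """
    if not lane.bands:
        raise EmptyLaneError(f"lane {lane.antibody_id}/{lane.sample_id} has no bands")
    best = max(lane.bands, key=lambda b: b.intensity)
    others = [b for b in lane.bands if b is not best]
    if not others:
        return best, True
    second = max(b.intensity for b in others)
    if second == best.intensity:
        return best, False  # tie: no single dominant band
    ratio_ok = best.intensity >= config.dominance_ratio * second
    gap = min(
        abs(math.log10(best.apparent_mw_kda) - math.log10(b.apparent_mw_kda))
        for b in others
    )
    return best, bool(ratio_ok and gap >= config.mw_gap_log10)


@dataclass
class SliceSet:
    """Capture-MS data for one cell line: an ordered stack of gel slices and,
    per protein, peptide-identification counts in each slice (optionally per
    replicate).

    Slice 1 is the top of the gel (highest MW); slice MW ranges are
    non-overlapping and strictly decreasing. ``counts[protein]`` is an array
    of shape (n_replicates, n_slices).
    """

    cell_line: str
    slices: list[tuple[int, float, float]]  # (index, mw_low_kda, mw_high_kda)
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.slices:
            raise DataValueError("slice set needs at least one slice")
        norm = []
        prev_low = math.inf
        for k, (idx, lo, hi) in enumerate(self.slices, start=1):
            if idx != k:
                raise DataValueError(f"slice indices must be 1..N in order, got {idx} at {k}")
            if not (0 < lo < hi):
                raise DataValueError(f"slice {idx}: need 0 < mw_low < mw_high")
            if hi > prev_low:
                raise DataValueError(f"slice {idx} overlaps the slice above it")
            prev_low = lo
            norm.append((idx, float(lo), float(hi)))
        self.slices = norm
        fixed = {}
        for prot, c in self.counts.items():
            arr = np.atleast_2d(np.asarray(c, dtype=int))
            if arr.shape[1] != self.n_slices:
                raise DataValueError(
                    f"counts for {prot!r} have {arr.shape[1]} slices, expected {self.n_slices}"
                )
            if np.any(arr < 0):
                raise DataValueError(f"negative peptide count for {prot!r}")
            fixed[prot] = arr
        self.counts = fixed

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def mw_range(self) -> tuple[float, float]:
        """(lowest, highest) MW covered by the gel, kDa."""
        return self.slices[-1][1], self.slices[0][2]

    def slice_of_mw(self, mw_kda: float) -> int:
        """1-based index of the slice whose MW range contains ``mw_kda``."""
        lo, hi = self.mw_range
        if not (lo <= mw_kda <= hi):
            raise GelRangeError(f"MW {mw_kda} kDa outside gel range [{lo}, {hi}]")
        for idx, s_lo, s_hi in self.slices:
            if s_lo <= mw_kda:  # first slice (from top) whose floor is below the MW
                return idx
        return self.slices[-1][0]


def make_slice_grid(
    n_slices: int = 50, mw_top_kda: float = 250.0, mw_bottom_kda: float = 10.0
) -> list[tuple[int, float, float]]:
    """Uniform-in-log10 slice boundaries from the top of the gel down.

    Mirrors how migration maps to MW: equal slice heights correspond to equal
    log-MW intervals.
    """
    if not (0 < mw_bottom_kda < mw_top_kda):
        raise DataValueError("need 0 < mw_bottom < mw_top")
    edges = np.logspace(math.log10(mw_top_kda), math.log10(mw_bottom_kda), n_slices + 1)
    return [(i + 1, float(edges[i + 1]), float(edges[i])) for i in range(n_slices)]


@dataclass
class VirtualWestern:
    """A protein's migration profile reconstructed from capture MS."""

    protein: str
    profile: np.ndarray  # peptide counts per slice, summed over replicates
    modal_slice: Optional[int]  # 1-based; None when undetected
    detected: bool


def build_virtual_western(slice_set: SliceSet, protein: str) -> VirtualWestern:
    """Sum peptide counts over replicates and locate the modal slice.

    Ties in the maximum break toward the lower index, i.e. the higher-MW
    slice; an all-zero profile means the protein was not detected. A protein
    absent from the slice set entirely raises
    :class:`ProteinNotCoveredError` — "not covered" is different evidence
    from "covered but never seen".
    """
    if protein not in slice_set.counts:
        raise ProteinNotCoveredError(
            f"protein {protein!r} not covered by capture MS of {slice_set.cell_line}"
        )
    profile = slice_set.counts[protein].sum(axis=0)
    if profile.sum() == 0:
        return VirtualWestern(protein, profile, None, False)
    modal = int(np.argmax(profile)) + 1  # argmax takes the first maximum
    return VirtualWestern(protein, profile, modal, True)


def capture_ms_match(
    band_mw: float, slice_set: SliceSet, protein: str, config: PillarConfig
) -> PillarResult:
    """Score the capture-MS pillar: does the antibody's band co-migrate with
    the protein's MS-identified peptides?

    * ``enhanced`` — band within ``mw_tolerance_slices`` of the modal slice
      and the protein detected (>=1 peptide in >=1 replicate);
    * ``uncertain`` — protein never detected, or band just outside the
      window (within twice the tolerance), which often reflects uncertainty
      in excising gel slices rather than off-target staining;
    * ``not_validated`` — band clearly elsewhere on the gel.

    ``crowding_flag`` marks bands in the 30-70 kDa region where many
    proteins co-migrate and concordance is weaker evidence.
    """
    band_slice = slice_set.slice_of_mw(band_mw)  # raises GelRangeError if outside
    vw = build_virtual_western(slice_set, protein)
    lo, hi = CROWDED_MW_RANGE_KDA
    crowding = lo <= band_mw <= hi
    metrics: dict[str, float] = {"crowding_flag": float(crowding)}
    if not vw.detected:
        return PillarResult(
            Pillar.CAPTURE_MS,
            PillarStatus.UNCERTAIN,
            metrics,
            note=f"{protein} not detected in capture MS of {slice_set.cell_line}",
        )
    offset = abs(band_slice - vw.modal_slice)
    metrics["mw_offset_slices"] = float(offset)
    metrics["modal_slice"] = float(vw.modal_slice)
    metrics["band_slice"] = float(band_slice)
    tol = config.mw_tolerance_slices
    if offset <= tol:
        status = PillarStatus.ENHANCED
        note = ""
    elif offset <= 2 * tol:
        status = PillarStatus.UNCERTAIN
        note = "band just outside the expected slice window"
    else:
        status = PillarStatus.NOT_VALIDATED
        note = f"band {offset} slices from the peptide modal slice"
    return PillarResult(Pillar.CAPTURE_MS, status, metrics, note=note)
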