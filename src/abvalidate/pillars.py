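"""Decision rules for the five validation pillars and their aggregation.

Each ``*_validate`` function maps measurements to a :class:`PillarResult`
carrying a four-way status. Thresholds are strict inequalities where the
criteria are worded strictly ("more than 25%", correlation "higher than 0.5"):
an antibody sitting exactly on a threshold does not pass. Degenerate inputs
that an assay can produce (no variability, no detection, failed reagents) map
to ``uncertain`` rather than raising — inconclusive is a first-class outcome.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datamodel import (
    AntibodyRecord,
    LaneProfile,
    Pillar,
    PillarConfig,
    PillarResult,
    PillarStatus,
    ValidationReport,
)
from .errors import DataValueError, DegenerateSeriesError, ParameterError, UsageError
from .gel import dominant_band

__all__ = [
    "SeriesPair",
    "pearson_r",
    "fold_change",
    "orthogonal_validate",
    "two_line_validate",
    "independent_validate",
    "genetic_validate",
    "recombinant_validate",
    "aggregate",
    "summarize_cohort",
]


@dataclass
class SeriesPair:
    """Aligned per-sample series: antibody band intensities vs an
    antibody-independent abundance (TPM, PRM ratio, or TMT intensity)."""

    antibody_band_series: np.ndarray
    orthogonal_series: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.antibody_band_series = np.asarray(self.antibody_band_series, dtype=float)
        self.orthogonal_series = np.asarray(self.orthogonal_series, dtype=float)
        n = len(self.sample_ids)
        if self.antibody_band_series.shape != (n,) or self.orthogonal_series.shape != (n,):
            raise DataValueError("series lengths must match sample_ids")
        if n < 2:
            raise DataValueError("a series pair needs at least 2 samples")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; invariant under positive affine transforms.

    Requires equal lengths >= 3 and nonzero variance in both series
    (:class:`DegenerateSeriesError` otherwise — upstream callers score that
    situation as ``uncertain``).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ParameterError("series lengths differ")
    if xa.size < 3:
        raise ParameterError(f"need >= 3 points for a correlation, got {xa.size}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateSeriesError("zero-variance series")
    return float(np.corrcoef(xa, ya)[0, 1])


def fold_change(values: Sequence[float], pseudocount: float = 0.0) -> float:
    """(max + pseudocount) / (min + pseudocount) over a nonnegative series."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ParameterError("empty series")
    hi = float(arr.max()) + pseudocount
    lo = float(arr.min()) + pseudocount
    if lo == 0:
        raise DegenerateSeriesError("all-zero series with zero pseudocount")
    return hi / lo


def _maybe_log(values: np.ndarray, config: PillarConfig) -> np.ndarray:
    if config.log_transform:
        return np.log2(values + config.pseudocount)
    return values


def orthogonal_validate(pair: SeriesPair, config: PillarConfig) -> PillarResult:
    """Panel-mode orthogonal validation (>= 3 samples).

    The correlation is only interpretable when the orthogonal series actually
    varies: below ``fold_min`` fold-change the pillar is ``uncertain`` (low
    variability gives low formal correlation regardless of specificity).
    Otherwise the antibody is ``enhanced`` when Pearson r strictly exceeds
    ``r_min`` and ``not_validated`` when it does not.
    """
    keep = ~(
        np.isnan(pair.antibody_band_series) | np.isnan(pair.orthogonal_series)
    )
    band = pair.antibody_band_series[keep]
    orth = pair.orthogonal_series[keep]
    metrics: dict[str, float] = {"n_samples": float(band.size)}
    if band.size < 3:
        return PillarResult(
            Pillar.ORTHOGONAL, PillarStatus.UNCERTAIN, metrics,
            note="fewer than 3 shared samples after dropping missing values",
        )
    try:
        fold = fold_change(orth, config.pseudocount)
    except DegenerateSeriesError:
        return PillarResult(
            Pillar.ORTHOGONAL, PillarStatus.UNCERTAIN, metrics,
            note="degenerate orthogonal series",
        )
    metrics["fold_change"] = fold
    if fold < config.fold_min:
        return PillarResult(
            Pillar.ORTHOGONAL, PillarStatus.UNCERTAIN, metrics,
            note=f"orthogonal fold-change {fold:.2f} below {config.fold_min:g}",
        )
    try:
        r = pearson_r(_maybe_log(band, config), _maybe_log(orth, config))
    except DegenerateSeriesError:
        return PillarResult(
            Pillar.ORTHOGONAL, PillarStatus.UNCERTAIN, metrics,
            note="zero-variance series",
        )
    metrics["pearson_r"] = r
    status = PillarStatus.ENHANCED if r > config.r_min else PillarStatus.NOT_VALIDATED
    return PillarResult(Pillar.ORTHOGONAL, status, metrics)


def two_line_validate(
    pair: SeriesPair, size_supported: bool, config: PillarConfig
) -> PillarResult:
    """Two-sample orthogonal validation (the standardized RT4/U-251 assay).

    With only two samples a correlation coefficient is meaningless, so the
    rule becomes: a fivefold RNA difference whose direction the bands follow
    -> ``enhanced``; below fivefold, a concordant trend still validates when
    the band size is independently supported (theoretical MW or capture MS);
    a contradicted ordering -> ``not_validated``; everything else
    ``uncertain``.
    """
    if len(pair.sample_ids) != 2:
        raise ParameterError("two-line mode needs exactly 2 samples")
    band = np.nan_to_num(pair.antibody_band_series, nan=0.0)
    orth = pair.orthogonal_series
    metrics: dict[str, float] = {}
    if band[0] == 0 and band[1] == 0:
        return PillarResult(
            Pillar.ORTHOGONAL, PillarStatus.UNCERTAIN, metrics,
            note="no band detected in either cell line",
        )
    if np.any(np.isnan(orth)):
        return PillarResult(
            Pillar.ORTHOGONAL, PillarStatus.UNCERTAIN, metrics,
            note="missing orthogonal measurement",
        )
    fold = fold_change(orth, config.pseudocount)
    metrics["fold_change"] = fold
    band_dir = np.sign(band[0] - band[1])
    orth_dir = np.sign(orth[0] - orth[1])
    metrics["trend_concordant"] = float(band_dir == orth_dir and band_dir != 0)
    if band_dir == 0 or orth_dir == 0:
        return PillarResult(
            Pillar.ORTHOGONAL, PillarStatus.UNCERTAIN, metrics, note="tied values"
        )
    if band_dir != orth_dir:
        return PillarResult(
            Pillar.ORTHOGONAL, PillarStatus.NOT_VALIDATED, metrics,
            note="band ordering contradicts orthogonal ordering",
        )
    if fold >= config.fold_min:
        return PillarResult(Pillar.ORTHOGONAL, PillarStatus.ENHANCED, metrics)
    if size_supported:
        return PillarResult(
            Pillar.ORTHOGONAL, PillarStatus.ENHANCED, metrics,
            note="trend concordant and band size supported",
        )
    return PillarResult(
        Pillar.ORTHOGONAL, PillarStatus.UNCERTAIN, metrics,
        note=f"fold-change {fold:.2f} below {config.fold_min:g} and size unsupported",
    )


def independent_validate(
    lanes_a: Sequence[LaneProfile],
    lanes_b: Sequence[LaneProfile],
    ab_a: AntibodyRecord,
    ab_b: AntibodyRecord,
    config: PillarConfig,
) -> PillarResult:
    """Compare staining patterns of two antibodies against the same target.

    The antibodies must have non-overlapping epitopes to count as
    independent. Validation requires the dominant bands to agree in apparent
    MW in every sample where both antibodies see a band, and the
    across-sample intensity profiles to agree (Pearson r > ``r_min`` with
    >= 3 shared detections, or matching ordering with 2). A partner antibody
    staining a different band in some sample marks the pair ``uncertain``
    with a discordance flag — the evidence points at the partner, not
    necessarily at the antibody under test.
    """
    if ab_a.target_gene != ab_b.target_gene:
        raise UsageError(
            f"antibodies target different genes: {ab_a.target_gene} vs {ab_b.target_gene}"
        )
    metrics: dict[str, float] = {}
    if ab_a.epitope_interval is None or ab_b.epitope_interval is None:
        return PillarResult(
            Pillar.INDEPENDENT, PillarStatus.UNCERTAIN, metrics,
            note="epitope interval missing; independence cannot be established",
        )
    s1, e1 = ab_a.epitope_interval
    s2, e2 = ab_b.epitope_interval
    if s1 <= e2 and s2 <= e1:
        return PillarResult(
            Pillar.INDEPENDENT, PillarStatus.UNCERTAIN, metrics,
            note="epitopes overlap; antibodies are not independent",
        )
    by_sample_a = {ln.sample_id: ln for ln in lanes_a}
    by_sample_b = {ln.sample_id: ln for ln in lanes_b}
    shared = [
        s for s in by_sample_a
        if s in by_sample_b and by_sample_a[s].bands and by_sample_b[s].bands
    ]
    metrics["n_shared_detections"] = float(len(shared))
    ints_a, ints_b = [], []
    discordant = []
    for s in shared:
        da, _ = dominant_band(by_sample_a[s], config)
        db, _ = dominant_band(by_sample_b[s], config)
        if abs(math.log10(da.apparent_mw_kda) - math.log10(db.apparent_mw_kda)) > config.mw_match_log10:
            discordant.append(s)
        ints_a.append(_normalized_intensity(da.intensity, by_sample_a[s]))
        ints_b.append(_normalized_intensity(db.intensity, by_sample_b[s]))
    if discordant:
        metrics["discordant_partner_flag"] = 1.0
        metrics["n_discordant_samples"] = float(len(discordant))
        return PillarResult(
            Pillar.INDEPENDENT, PillarStatus.UNCERTAIN, metrics,
            note=f"dominant-band MW disagreement in: {', '.join(sorted(discordant))}",
        )
    if len(shared) >= 3:
        try:
            r = pearson_r(ints_a, ints_b)
        except DegenerateSeriesError:
            return PillarResult(
                Pillar.INDEPENDENT, PillarStatus.UNCERTAIN, metrics,
                note="zero-variance intensity profile",
            )
        metrics["pearson_r"] = r
        if r > config.r_min:
            return PillarResult(Pillar.INDEPENDENT, PillarStatus.ENHANCED, metrics)
        return PillarResult(
            Pillar.INDEPENDENT, PillarStatus.UNCERTAIN, metrics,
            note="intensity profiles poorly correlated",
        )
    if len(shared) == 2:
        d_a = np.sign(ints_a[0] - ints_a[1])
        d_b = np.sign(ints_b[0] - ints_b[1])
        if d_a == d_b and d_a != 0:
            return PillarResult(Pillar.INDEPENDENT, PillarStatus.ENHANCED, metrics)
        return PillarResult(
            Pillar.INDEPENDENT, PillarStatus.UNCERTAIN, metrics,
            note="intensity ordering does not agree",
        )
    return PillarResult(
        Pillar.INDEPENDENT, PillarStatus.UNCERTAIN, metrics,
        note="fewer than 2 samples with bands from both antibodies",
    )


def _normalized_intensity(intensity: float, lane: LaneProfile) -> float:
    if lane.loading_control_intensity:
        return intensity / lane.loading_control_intensity
    return intensity


def genetic_validate(
    control_intensity: float,
    kd_intensities: Sequence[float],
    config: PillarConfig,
    kd_verified: bool = False,
) -> PillarResult:
    """siRNA knockdown pillar.

    At least one of the (up to two) siRNA reagents must reduce the
    loading-control-normalized target band by strictly more than
    ``kd_min_fraction`` of the control signal. A failed knockdown is
    ``uncertain`` — siRNA efficacy, not antibody specificity, is the usual
    culprit — unless ``kd_verified`` asserts the knockdown is independently
    known to have worked, in which case it becomes ``not_validated``.
    """
    if not (control_intensity > 0):
        raise DataValueError(f"control intensity must be positive, got {control_intensity}")
    kds = np.asarray(kd_intensities, dtype=float)
    if kds.size not in (1, 2):
        raise ParameterError(f"expected 1-2 knockdown measurements, got {kds.size}")
    if np.any(kds < 0):
        raise DataValueError("knockdown intensities must be >= 0")
    reduction = 1.0 - float(kds.min()) / control_intensity
    metrics = {"kd_fraction": reduction}
    if reduction > config.kd_min_fraction:
        return PillarResult(Pillar.GENETIC, PillarStatus.ENHANCED, metrics)
    if kd_verified:
        return PillarResult(
            Pillar.GENETIC, PillarStatus.NOT_VALIDATED, metrics,
            note="band unresponsive to a verified knockdown",
        )
    return PillarResult(
        Pillar.GENETIC, PillarStatus.UNCERTAIN, metrics,
        note=f"max reduction {reduction:.0%} does not exceed {config.kd_min_fraction:.0%}",
    )


def recombinant_validate(
    control_lane: LaneProfile,
    oe_lane: LaneProfile,
    expressed: bool,
    config: PillarConfig,
) -> PillarResult:
    """Recombinant-overexpression pillar (HEK 293 with/without expression vector).

    The antibody must show a strong band under recombinant expression and no
    or a much fainter band in the control: ``enhanced`` when the
    overexpressed dominant band is at least ``oe_min_ratio`` times the
    MW-matched control band (an absent control band counts as the
    pseudocount); ``not_validated`` when the control matches or exceeds it.
    If the construct failed to express, nothing can be concluded.
    """
    if not expressed:
        return PillarResult(
            Pillar.RECOMBINANT, PillarStatus.UNCERTAIN, {},
            note="no expression in the recombinant cell line",
        )
    if not oe_lane.bands:
        return PillarResult(
            Pillar.RECOMBINANT, PillarStatus.NOT_VALIDATED, {},
            note="no band despite recombinant expression",
        )
    oe_band, _ = dominant_band(oe_lane, config)
    matched = [
        b.intensity
        for b in control_lane.bands
        if abs(math.log10(b.apparent_mw_kda) - math.log10(oe_band.apparent_mw_kda))
        <= config.mw_match_log10
    ]
    ctrl = max(matched) if matched else config.pseudocount
    ratio = oe_band.intensity / ctrl if ctrl > 0 else math.inf
    metrics = {"oe_ratio": ratio, "control_band_present": float(bool(matched))}
    if ctrl >= oe_band.intensity:
        return PillarResult(
            Pillar.RECOMBINANT, PillarStatus.NOT_VALIDATED, metrics,
            note="control band at least as strong as the overexpressed band",
        )
    if oe_band.intensity >= config.oe_min_ratio * ctrl:
        return PillarResult(Pillar.RECOMBINANT, PillarStatus.ENHANCED, metrics)
    return PillarResult(
        Pillar.RECOMBINANT, PillarStatus.UNCERTAIN, metrics,
        note=f"overexpression ratio {ratio:.1f} below {config.oe_min_ratio:g}",
    )


def aggregate(results: Sequence[PillarResult], antibody_id: str = "") -> ValidationReport:
    """Merge per-pillar results into one report; untried pillars are ``not_done``."""
    seen: dict[Pillar, PillarResult] = {}
    for r in results:
        if r.pillar in seen:
            raise UsageError(f"duplicate result for pillar {r.pillar.value}")
        seen[r.pillar] = r
    full = [
        seen.get(p, PillarResult(p, PillarStatus.NOT_DONE)) for p in Pillar
    ]
    return ValidationReport(antibody_id=antibody_id, pillar_results=full)


def summarize_cohort(reports: Sequence[ValidationReport]) -> dict:
    """Cohort tallies: how many antibodies reached >= k enhanced pillars, and
    per-pillar enhanced counts."""
    ge = {k: sum(1 for r in reports if r.n_enhanced >= k) for k in range(1, 6)}
    per_pillar = {
        p.value: sum(
            1 for r in reports if r.status_of(p) is PillarStatus.ENHANCED
        )
        for p in Pillar
    }
    return {
        "n_reports": len(reports),
        "validated_ge": ge,
        "per_pillar_enhanced": per_pillar,
    }
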