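"""Seeded synthetic-data generators with ground truth.

The generators emulate the study design the validation pipeline is built for:
an eight-cell-line panel with correlated lognormal RNA/protein abundances,
Western-blot band intensities proportional to target abundance with
multiplicative densitometry noise, capture-MS gel-slice peptide-count
profiles, and knockdown/overexpression perturbations. Every artifact comes
with a truth label so each pillar's decision rule can be scored against what
the generator actually did (specific antibody, off-target antibody, shifted
band, ...).

All draws flow through ``numpy.random.default_rng`` seeded from the scenario
seed plus a fixed per-generator stream index, so every artifact is
bit-reproducible for a given seed and parameter set.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .datamodel import (
    AbundancePanel,
    Band,
    LaneProfile,
    MeasurementKind,
    PillarConfig,
    PillarStatus,
    Sample,
)
from .errors import ParameterError
from .gel import SliceSet, make_slice_grid, theoretical_mw
from .pillars import (
    SeriesPair,
    genetic_validate,
    orthogonal_validate,
    recombinant_validate,
)
from .gel import capture_ms_match

__all__ = [
    "CELL_LINES",
    "ScenarioLabel",
    "Scenario",
    "make_scenario",
    "gen_protein_sequences",
    "gen_expression_panel",
    "gen_lanes",
    "gen_slice_set",
    "gen_knockdown",
    "gen_overexpression",
    "orthogonal_cohort",
    "capture_cohort",
    "knockdown_cohort",
    "overexpression_cohort",
]

# The targeted-proteomics cell-line panel.
CELL_LINES = ["A431", "A549", "HEK 293", "HeLa", "Hep G2", "RT4", "SH-SY5Y", "U-2 OS"]

# Stream indices so independent generators never share a random stream.
_STREAM_PANEL, _STREAM_SEQ, _STREAM_LANES, _STREAM_SLICES, _STREAM_KD, _STREAM_OE = range(6)

# Proteome-average amino-acid frequencies (approximate human values), used to
# draw random protein sequences whose mean residue mass is realistic (~111 Da).
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_FREQ = np.array([
    0.070, 0.023, 0.047, 0.071, 0.036, 0.066, 0.026, 0.043, 0.057, 0.100,
    0.021, 0.036, 0.063, 0.048, 0.056, 0.083, 0.053, 0.060, 0.012, 0.027,
])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

_GEL_TOP_KDA = 250.0
_GEL_BOTTOM_KDA = 10.0
_N_SLICES_DEFAULT = 50


class ScenarioLabel(str, Enum):
    SPECIFIC = "specific"            # band tracks the target protein
    OFF_TARGET = "off_target"        # band tracks an unrelated decoy protein
    MW_SHIFTED = "mw_shifted"        # band displaced from the target's MW
    MULTI_BAND = "multi_band"        # dominant target band plus weaker extras
    LOW_VARIABILITY = "low_variability"  # target barely varies across the panel


@dataclass
class Scenario:
    """One simulated antibody/target situation with its noise model.

    ``fold_range_log2`` bounds the spread of per-sample log2 abundances (the
    orthogonal fold-change can never exceed ``2**fold_range_log2``);
    ``rna_protein_rho`` couples protein to RNA on the log scale;
    ``noise_sd_log`` is the SD (natural log) of the multiplicative
    densitometry noise on band intensities.
    """

    label: ScenarioLabel
    target_gene: str = "TARG1"
    decoy_gene: Optional[str] = None
    mw_shift_kda: Optional[float] = None
    noise_sd_log: float = 0.2
    rna_protein_rho: float = 0.9
    n_samples: int = 8
    fold_range_log2: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.label = ScenarioLabel(self.label)
        if self.label is ScenarioLabel.OFF_TARGET:
            if not self.decoy_gene or self.decoy_gene == self.target_gene:
                raise ParameterError("off_target needs a decoy_gene distinct from the target")
        if not (-1.0 <= self.rna_protein_rho <= 1.0):
            raise ParameterError(f"rna_protein_rho must be in [-1,1], got {self.rna_protein_rho}")
        if self.noise_sd_log < 0 or self.fold_range_log2 < 0:
            raise ParameterError("noise parameters must be >= 0")
        if self.n_samples < 2:
            raise ParameterError("need at least 2 samples")

    def source_gene(self) -> str:
        """The gene whose abundance the simulated band actually follows."""
        if self.label is ScenarioLabel.OFF_TARGET:
            return self.decoy_gene  # type: ignore[return-value]
        return self.target_gene


def make_scenario(label: ScenarioLabel | str, seed: int = 0, **kw) -> Scenario:
    """Scenario with per-label defaults.

    ``low_variability`` defaults to ``fold_range_log2 = 1.0`` so the
    orthogonal series' fold-change stays below the fivefold gate;
    ``off_target`` gets a decoy gene.
    """
    label = ScenarioLabel(label)
    params: dict = {"label": label, "seed": seed}
    if label is ScenarioLabel.OFF_TARGET:
        params.setdefault("decoy_gene", "DECOY1")
    if label is ScenarioLabel.LOW_VARIABILITY:
        params.setdefault("fold_range_log2", 1.0)
    params.update(kw)
    return Scenario(**params)


def _rng(scenario: Scenario, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(scenario.seed), stream])


def gen_protein_sequences(
    genes: Sequence[str], seed: int, min_len: int = 100, max_len: int = 1700
) -> dict[str, str]:
    """Random protein sequences of proteome-like composition, one per gene.

    Lengths are uniform over [min_len, max_len], keeping theoretical MWs
    (~11-190 kDa) inside the simulated gel's 10-250 kDa window.
    """
    rng = np.random.default_rng([int(seed), _STREAM_SEQ])
    out = {}
    for gene in genes:
        n = int(rng.integers(min_len, max_len + 1))
        out[gene] = "".join(rng.choice(_AA, size=n, p=_AA_FREQ))
    return out


def gen_expression_panel(
    n_genes: int, scenario: Scenario
) -> tuple[AbundancePanel, AbundancePanel]:
    """Correlated (RNA TPM, protein PRM-ratio) panels across the cell lines.

    Per gene, sample log2 RNA offsets are uniform over ``fold_range_log2``;
    the protein log-abundance is ``rho * standardized(RNA) +
    sqrt(1 - rho^2) * noise`` rescaled to the RNA spread and back-transformed.
    Gene order: target, decoy (if any), then filler genes.
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    genes = [scenario.target_gene]
    if scenario.decoy_gene:
        genes.append(scenario.decoy_gene)
    genes += [f"FILL{i:04d}" for i in range(n_genes - len(genes))]
    genes = genes[:max(n_genes, len(genes))]
    rng = _rng(scenario, _STREAM_PANEL)
    n_s = scenario.n_samples
    sample_names = CELL_LINES[:n_s] + [f"CL{i + 1}" for i in range(max(0, n_s - len(CELL_LINES)))]
    samples = [Sample(s) for s in sample_names]
    rho = scenario.rna_protein_rho
    rna_rows, prot_rows = [], []
    for _ in genes:
        u = rng.uniform(0.0, scenario.fold_range_log2, size=n_s)
        base_rna = rng.uniform(2.0, 8.0)
        rna_log2 = base_rna + u
        sd_u = float(u.std())
        z = (u - u.mean()) / sd_u if sd_u > 0 else np.zeros(n_s)
        eps = rng.standard_normal(n_s)
        base_prot = rng.uniform(-2.0, 2.0)
        prot_log2 = base_prot + sd_u * (rho * z + math.sqrt(1.0 - rho * rho) * eps)
        rna_rows.append(2.0 ** rna_log2)
        prot_rows.append(2.0 ** prot_log2)
    rna = AbundancePanel(MeasurementKind.TPM, list(genes), samples, np.array(rna_rows))
    prot = AbundancePanel(
        MeasurementKind.PRM_RATIO, list(genes), list(samples), np.array(prot_rows)
    )
    return rna, prot


def _slice_width_log10(n_slices: int = _N_SLICES_DEFAULT) -> float:
    return math.log10(_GEL_TOP_KDA / _GEL_BOTTOM_KDA) / n_slices


def _shifted_mw(true_mw: float, scenario: Scenario, n_slices: int = _N_SLICES_DEFAULT) -> float:
    """Band MW for the mw_shifted scenario.

    An explicit ``mw_shift_kda`` wins; otherwise displace by 4 slice-widths in
    log space toward the gel centre, so the band stays on the gel and remains
    >= 3 slices from the true position even if noise nudges the modal slice.
    """
    if scenario.mw_shift_kda is not None:
        return true_mw + scenario.mw_shift_kda
    shift = 4 * _slice_width_log10(n_slices)
    centre = math.sqrt(_GEL_TOP_KDA * _GEL_BOTTOM_KDA)
    direction = 1.0 if true_mw < centre else -1.0
    return 10 ** (math.log10(true_mw) + direction * shift)


def gen_lanes(
    scenario: Scenario,
    panels: tuple[AbundancePanel, AbundancePanel],
    mw_by_gene: Optional[dict[str, float]] = None,
    antibody_id: str = "ab1",
    detection_floor: float = 0.0,
) -> tuple[list[LaneProfile], dict]:
    """Western-blot lanes for one antibody across the sample panel.

    Band intensity is proportional to the source protein's abundance with
    multiplicative lognormal noise; which gene the band follows, and where it
    sits on the gel, depend on the scenario label. Proteins below
    ``detection_floor`` produce no band (empty lane), exercising the
    missing-data paths downstream.
    """
    rna, protein = panels
    source = scenario.source_gene()
    if source not in protein.genes:
        raise ParameterError(f"panel lacks the source gene {source!r}")
    if mw_by_gene is None:
        seqs = gen_protein_sequences(sorted(set(protein.genes)), scenario.seed)
        mw_by_gene = {g: theoretical_mw(s) for g, s in seqs.items()}
    target_mw = mw_by_gene[scenario.target_gene]
    band_mw = target_mw
    if scenario.label is ScenarioLabel.MW_SHIFTED:
        band_mw = _shifted_mw(target_mw, scenario)
    rng = _rng(scenario, _STREAM_LANES)
    series = protein.series(source)
    scale = 1000.0 / max(float(np.nanmean(series)), 1e-12)
    lanes = []
    for j, sid in enumerate(protein.sample_ids):
        value = series[j]
        bands = []
        if not np.isnan(value) and value >= detection_floor:
            noise = math.exp(rng.normal(0.0, scenario.noise_sd_log)) if scenario.noise_sd_log else 1.0
            main = Band(band_mw, scale * value * noise)
            bands.append(main)
            if scenario.label is ScenarioLabel.MULTI_BAND:
                for factor in (1.5, 0.6):
                    bands.append(Band(band_mw * factor, 0.2 * main.intensity))
        lanes.append(LaneProfile(antibody_id, sid, bands))
    truth = {
        "label": scenario.label.value,
        "target_gene": scenario.target_gene,
        "source_gene": source,
        "band_mw_kda": band_mw,
        "target_mw_kda": target_mw,
    }
    return lanes, truth


def gen_slice_set(
    panels: tuple[AbundancePanel, AbundancePanel],
    sequences: dict[str, str],
    n_slices: int = _N_SLICES_DEFAULT,
    spillover: float = 0.25,
    seed: int = 0,
    cell_line: str = "RT4",
    n_replicates: int = 3,
    expected_peptides: float = 18.0,
    detection_floor: float = 0.0,
) -> tuple[SliceSet, dict[str, int]]:
    """Capture-MS peptide counts over a 50-slice gel, with truth slices.

    Expected counts concentrate in the slice containing each protein's
    theoretical MW, decaying geometrically (factor ``spillover``) into
    neighbouring slices; observed counts are Poisson draws split over
    replicates. Proteins whose mean abundance falls below
    ``detection_floor`` (or is zero) yield all-zero counts.
    """
    if not (0.0 <= spillover < 1.0):
        raise ParameterError("spillover must be in [0, 1)")
    _, protein = panels
    grid = make_slice_grid(n_slices, _GEL_TOP_KDA, _GEL_BOTTOM_KDA)
    probe = SliceSet(cell_line=cell_line, slices=grid, counts={})
    rng = np.random.default_rng([int(seed), _STREAM_SLICES])
    counts: dict[str, np.ndarray] = {}
    truth: dict[str, int] = {}
    for gene, seq in sequences.items():
        mw = theoretical_mw(seq)
        true_slice = probe.slice_of_mw(mw)  # raises GelRangeError when off-gel
        truth[gene] = true_slice
        abundance = (
            float(np.nanmean(protein.series(gene))) if gene in protein.genes else 0.0
        )
        arr = np.zeros((n_replicates, n_slices), dtype=int)
        if abundance > 0 and abundance >= detection_floor:
            d = np.abs(np.arange(1, n_slices + 1) - true_slice)
            weights = spillover ** d if spillover > 0 else (d == 0).astype(float)
            weights = weights / weights.sum()
            lam = expected_peptides * weights / n_replicates
            arr = rng.poisson(lam, size=(n_replicates, n_slices))
        counts[gene] = arr
    return SliceSet(cell_line=cell_line, slices=grid, counts=counts), truth


def gen_knockdown(
    scenario: Scenario, efficiency_pair: Sequence[float], seed: Optional[int] = None
) -> tuple[float, list[float], dict]:
    """Control and post-knockdown band intensities for 1-2 siRNA reagents.

    A specific antibody's band drops in proportion to the knockdown
    efficiency; an off-target antibody's band ignores it. Multiplicative
    lognormal noise as for lane intensities.
    """
    effs = [float(e) for e in efficiency_pair]
    if not effs or len(effs) > 2 or any(not (0.0 <= e <= 1.0) for e in effs):
        raise ParameterError("need 1-2 knockdown efficiencies in [0, 1]")
    rng = np.random.default_rng([int(seed if seed is not None else scenario.seed), _STREAM_KD])
    control = 1.0
    kds = []
    for e in effs:
        responsive = scenario.label is not ScenarioLabel.OFF_TARGET
        base = control * (1.0 - e) if responsive else control
        noise = math.exp(rng.normal(0.0, scenario.noise_sd_log)) if scenario.noise_sd_log else 1.0
        kds.append(base * noise)
    truth = {
        "label": scenario.label.value,
        "responsive": scenario.label is not ScenarioLabel.OFF_TARGET,
        "best_efficiency": max(effs),
    }
    return control, kds, truth


def gen_overexpression(
    scenario: Scenario,
    induction_fold: float,
    seed: Optional[int] = None,
    control_expressed: bool = True,
    target_mw_kda: float = 50.0,
) -> tuple[LaneProfile, LaneProfile, dict]:
    """Matched control / overexpression lanes (HEK 293 with/without vector).

    A specific antibody's band scales by ``induction_fold`` under
    overexpression; an off-target band does not respond. With
    ``control_expressed=False`` the control lane carries no band at all
    (target absent from the parental line).
    """
    if induction_fold < 1.0:
        raise ParameterError("induction_fold must be >= 1")
    rng = np.random.default_rng([int(seed if seed is not None else scenario.seed), _STREAM_OE])
    base = 100.0

    def noisy(v: float) -> float:
        if scenario.noise_sd_log:
            return v * math.exp(rng.normal(0.0, scenario.noise_sd_log))
        return v

    responsive = scenario.label is not ScenarioLabel.OFF_TARGET
    ctrl_bands = [Band(target_mw_kda, noisy(base))] if control_expressed else []
    oe_intensity = base * induction_fold if responsive else base
    if not control_expressed and not responsive:
        oe_bands: list[Band] = []  # off-target of an unexpressed gene: nothing anywhere
    else:
        ref = base if control_expressed else base * (induction_fold if responsive else 1.0)
        oe_bands = [Band(target_mw_kda, noisy(oe_intensity if control_expressed else ref))]
    control_lane = LaneProfile("ab1", "HEK293_control", ctrl_bands)
    oe_lane = LaneProfile("ab1", "HEK293_oe", oe_bands)
    truth = {"label": scenario.label.value, "responsive": responsive}
    return control_lane, oe_lane, truth


# ---------------------------------------------------------------------------
# Cohort harnesses: many simulated antibodies of one scenario, pushed through
# the corresponding pillar's decision rule. These are what the recovery
# checks and the acceptance workflow run.
# ---------------------------------------------------------------------------


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(int(seed)).integers(0, 2**31 - 1, size=n)


def orthogonal_cohort(
    label: ScenarioLabel | str,
    n_antibodies: int = 200,
    seed: int = 0,
    config: Optional[PillarConfig] = None,
) -> Counter:
    """Simulate ``n_antibodies`` of one scenario and score the orthogonal
    pillar against the PRM protein panel; returns status counts."""
    config = config or PillarConfig()
    statuses: Counter = Counter()
    for s in _spawn_seeds(seed, n_antibodies):
        scenario = make_scenario(label, seed=int(s))
        panels = gen_expression_panel(2 if scenario.decoy_gene else 1, scenario)
        lanes, _ = gen_lanes(scenario, panels)
        _, protein = panels
        band = np.array(
            [ln.bands[0].intensity if ln.bands else np.nan for ln in lanes]
        )
        pair = SeriesPair(band, protein.series(scenario.target_gene), protein.sample_ids)
        statuses[orthogonal_validate(pair, config).status] += 1
    return statuses


def capture_cohort(
    label: ScenarioLabel | str = ScenarioLabel.SPECIFIC,
    n_antibodies: int = 200,
    seed: int = 0,
    config: Optional[PillarConfig] = None,
) -> Counter:
    """Capture-MS recovery: band placed at (or shifted from) the target's
    theoretical MW, scored against a simulated 50-slice peptide profile."""
    config = config or PillarConfig()
    statuses: Counter = Counter()
    for s in _spawn_seeds(seed, n_antibodies):
        scenario = make_scenario(label, seed=int(s))
        panels = gen_expression_panel(1, scenario)
        seqs = gen_protein_sequences([scenario.target_gene], scenario.seed)
        lanes, truth = gen_lanes(scenario, panels, {scenario.target_gene: theoretical_mw(seqs[scenario.target_gene])})
        slice_set, _ = gen_slice_set(panels, seqs, seed=scenario.seed)
        result = capture_ms_match(truth["band_mw_kda"], slice_set, scenario.target_gene, config)
        statuses[result.status] += 1
    return statuses


def knockdown_cohort(
    label: ScenarioLabel | str = ScenarioLabel.SPECIFIC,
    n_antibodies: int = 200,
    seed: int = 0,
    config: Optional[PillarConfig] = None,
    efficiencies: tuple[float, float] = (0.6, 0.3),
) -> Counter:
    config = config or PillarConfig()
    statuses: Counter = Counter()
    for s in _spawn_seeds(seed, n_antibodies):
        scenario = make_scenario(label, seed=int(s))
        control, kds, _ = gen_knockdown(scenario, efficiencies)
        statuses[genetic_validate(control, kds, config).status] += 1
    return statuses


def overexpression_cohort(
    label: ScenarioLabel | str = ScenarioLabel.SPECIFIC,
    n_antibodies: int = 200,
    seed: int = 0,
    config: Optional[PillarConfig] = None,
    induction_fold: float = 20.0,
) -> Counter:
    config = config or PillarConfig()
    statuses: Counter = Counter()
    for s in _spawn_seeds(seed, n_antibodies):
        scenario = make_scenario(label, seed=int(s))
        ctrl, oe, _ = gen_overexpression(scenario, induction_fold)
        statuses[recombinant_validate(ctrl, oe, expressed=True, config=config).status] += 1
    return statuses
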