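# Methods

This note documents the models, decision rules, numerical choices, and the
synthetic-data design behind `abvalidate`, and what the passing tests do and
do not establish about real data.

## The decision model

An antibody is assessed per *pillar*; each pillar maps its measurements to
one of four statuses. Two principles shape every rule:

* **Strict thresholds.** The criteria are worded strictly ("more than 25%",
  correlation "higher than 0.5"), so the implementation uses strict
  inequalities: a knockdown of exactly 25%, or *r* of exactly 0.5, does not
  pass. A fivefold orthogonal range exactly is, however, *not* "less than
  fivefold" and admits the antibody to the correlation test.
* **`uncertain` is a first-class outcome, not an error.** Degenerate biology
  — an orthogonal series that barely varies, a protein never detected by
  capture MS, an siRNA that may simply not have worked, a construct that did
  not express — yields `uncertain`, never an exception and never
  `not_validated`. Only evidence that actively contradicts specificity
  (anti-tracking intensities, a band clearly elsewhere on the gel, a control
  band as strong as the overexpressed one) demotes to `not_validated`.

### Orthogonal (panel mode)

Missing samples are dropped pairwise; fewer than three shared samples is
`uncertain`. The fold-change gate `(max+ψ)/(min+ψ) ≥ fold_min` (pseudocount
ψ = 0.1 by default) applies to the *orthogonal* series: a correlation
against a flat series is statistically meaningless regardless of the
antibody. Past the gate, Pearson *r* strictly above `r_min = 0.5` is
`enhanced`, otherwise `not_validated`. Correlation is computed on linear
values by default; `log_transform` switches to `log2(value + ψ)`. Band
intensities are divided by the loading-control intensity when one is
recorded; the statistic is scale-invariant, so the normalization affects
only multi-lane comparability, not single-pair verdicts.

### Two-cell-line mode

With two samples a correlation coefficient is meaningless, so the rule is
ordinal: fivefold orthogonal difference plus concordant band ordering is
`enhanced`; below fivefold, concordant ordering still validates when the
band size is independently supported (theoretical MW or capture MS);
contradicted ordering is `not_validated`; ties and unsupported low-fold
trends are `uncertain`.

### Capture MS

The *virtual Western* sums peptide counts over replicates per gel slice;
the modal slice is the argmax, ties broken toward the lower index (higher
MW) for determinism. The band's slice is found from its apparent MW on the
same slice grid. Offset ≤ `mw_tolerance_slices` (default 1) with the
protein detected (≥ 1 peptide in ≥ 1 replicate — identification, not
quantification) is `enhanced`; offset within twice the tolerance is
`uncertain`, reflecting that gel-excision uncertainty often places bands
just outside the expected window; larger offsets are `not_validated`.
Bands between 30 and 70 kDa carry a `crowding_flag`: many unrelated
proteins co-migrate there, so concordance is weaker evidence. One cell
line's support suffices; the CLI evaluates each available cell line and
keeps the best outcome.

### Independent antibody

Requires stated, non-overlapping epitope intervals (1-based inclusive
amino-acid coordinates); overlap or missing intervals mean independence
cannot be established (`uncertain`). Across the samples where both
antibodies detect a band, the dominant bands must agree in apparent MW
within `mw_match_log10 = 0.1` (about one ladder interval); any disagreement
flags the discordant partner and scores `uncertain` — the evidence points
at the partner's non-specific staining rather than the antibody under
test. With agreement, ≥ 3 shared detections use Pearson *r* > `r_min`; two
use strict ordering agreement.

### Genetic and recombinant

Genetic: maximum reduction `1 − min(kd)/control` must strictly exceed
`kd_min_fraction = 0.25`. Failure is `uncertain` by default (siRNA efficacy
is the usual culprit); the `kd_verified` flag re-maps failure to
`not_validated` when the knockdown is independently known to have worked.
Recombinant: the overexpressed dominant band must be ≥ `oe_min_ratio = 5`
times the MW-matched control band (absent control band counts as the
pseudocount); a control band at least as strong is `not_validated`; ratios
between 1 and 5 are `uncertain`.

### Dominant band

Only the strongest-stained band is eligible for validation, and only when
clearly separated: ≥ `dominance_ratio = 2` times the runner-up intensity
*and* ≥ `mw_gap_log10 = 0.05` (≈ 12% MW difference) from the nearest other
band. An exact intensity tie is never separated. The gap and match
tolerances (`mw_gap_log10`, `mw_match_log10`) are this package's
operationalization — "clearly separated" and "the same band" are not
quantified in the literature the rules come from — and are configurable.

## Gel physics

Ladder calibration interpolates migration linearly in log10(MW) between
knots, the standard reading of SDS-PAGE mobility; extrapolation beyond the
calibrated range is refused unless explicitly allowed (end-segment slope).
Theoretical MW is the sum of *average* (not monoisotopic) residue masses
plus one water — gel-scale physics concerns average isotopologues — with no
PTMs; glycine alone is 75.0672 Da. The simulated gel spans 250 → 10 kDa in
50 slices uniform in log10(MW), mirroring the migration/MW relation; the
slice type nevertheless carries explicit per-slice MW ranges so non-uniform
real grids are representable.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions the recovery checks run under:

* **Expression panels** — eight cell lines; per gene, sample log2 RNA
  offsets uniform over `fold_range_log2 = 6`; protein log-abundance
  `ρ·standardized(RNA) + √(1−ρ²)·ε` with `ρ = 0.9`, rescaled to the RNA
  spread and exponentiated. Lognormal abundance is the standard model for
  expression data.
* **Bands** — intensity proportional to the source protein's abundance with
  multiplicative lognormal noise, SD 0.2 (natural log), the standard model
  for densitometry. The source is the target (specific), a decoy
  (off_target), or the target with the band displaced (mw_shifted — by
  4 slice-widths toward the gel centre when no explicit shift is given, so
  the offset stays ≥ 3 slices even if counting noise moves the modal slice
  by one, and the band stays on the gel). `multi_band` adds two weaker
  flanking bands; `low_variability` uses `fold_range_log2 = 1`, keeping the
  orthogonal fold-change below 5 with overwhelming probability so the
  variability gate fires deterministically in practice.
* **Capture MS** — expected peptide counts concentrate in the slice
  containing the theoretical MW with geometric spillover (factor 0.25) to
  neighbours, total expectation 18 peptides split over three Poisson
  replicates; zero-abundance proteins give all-zero counts. A detection
  floor (abundance below which bands/peptides vanish) exercises the
  missing-data paths.
* **Perturbations** — knockdown intensities `control·(1−efficiency)·noise`
  for responsive (specific) antibodies and `control·noise` for off-target
  ones; overexpression scales the band by the induction fold.

Every generator is bit-reproducible given a seed (per-generator random
streams are derived from the seed plus a fixed stream index) and emits
ground-truth labels sufficient for confusion matrices.

What passing recovery tests show: the decision rules separate the failure
modes they encode, at realistic noise, on panels of this size. What they do
not show: robustness to real-data pathologies the generator omits —
isoform mixtures, partial proteolysis, batch effects between the antibody
and orthogonal measurements, non-lognormal heavy tails, correlated decoys
(an off-target protein co-regulated with the target would evade the
orthogonal pillar by construction), or densitometry saturation.

## Problem sizes and numerical choices

Recovery cohorts use 200 antibodies per scenario — large enough that the
binomial uncertainty on a recovery rate is ≈ 2–3 points, small enough that
the full suite runs in seconds. The orthogonal recovery is scored against
the PRM protein panel (the primary orthogonal route; the RNA route differs
only in the series supplied). Correlations use the product-moment formula
via numpy; an independently coded sum-of-products oracle agrees to 1e-12 in
the tests. Theoretical-MW additivity holds to 1e-9 kDa. Modal-slice ties
and argmax ties break toward the lower index. Panel values may contain NaN
for missing measurements; all parsers reject negative abundances, duplicate
gene/sample identifiers, and rows mixing migration with apparent MW, each
with a named exception.

## Cohort re-tally

`cohort.run_reproduction` recomputes orthogonal-validation tallies
(passes/failures vs proteomics, passes/low-fold/failures vs RNA, genes with
TPM > 10 in at least one line) from externally supplied tables. Because the
original analyses' transform choices are not recorded, linear and log2
variants are both reported. The module is exercised in the test suite on a
synthetic stand-in cohort with designed outcomes; with no data directory it
reports `data unavailable` rather than failing, so the package never
depends on downloads.

## Known limitations

* The independent-antibody pillar assumes one lane profile per sample per
  antibody and stated epitope intervals; epitope mapping itself is out of
  scope.
* Capture-MS consumes precomputed peptide counts; digestion simulation,
  FDR control, and isoform-aware peptide mapping are out of scope.
* Identifier mapping is not performed; gene symbols are opaque strings.
* The aggregation counts `enhanced` pillars only; it does not weight
  pillars by evidential strength, although the capture-MS crowding flag and
  discordance flags are carried in the metrics for downstream use.
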