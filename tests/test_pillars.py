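"""Pillar decision rules: oracle equivalence for the statistics, strict
threshold behaviour at the published cut-offs, and the invariances the
decision pipeline promises (scale invariance, threshold monotonicity)."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from abvalidate import (
    AntibodyRecord,
    Band,
    LaneProfile,
    Pillar,
    PillarConfig,
    PillarResult,
    PillarStatus,
    SeriesPair,
    ValidationReport,
    aggregate,
    fold_change,
    genetic_validate,
    independent_validate,
    orthogonal_validate,
    pearson_r,
    recombinant_validate,
    summarize_cohort,
    two_line_validate,
)
from abvalidate.errors import (
    DataValueError,
    DegenerateSeriesError,
    ParameterError,
    UsageError,
)

PANEL = ["A431", "A549", "HEK 293", "HeLa", "Hep G2", "RT4", "SH-SY5Y", "U-2 OS"]
FIVE_SAMPLES = ["RT4", "U-251", "plasma", "liver", "tonsil"]


def pearson_brute(x, y):
    """Independent sum-of-products oracle for the correlation coefficient."""
    n = len(x)
    sx = sum(x); sy = sum(y)
    sxx = sum(a * a for a in x); syy = sum(b * b for b in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


class TestPearson:
    def test_identity_and_reversal(self):
        assert pearson_r([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_oracle_equivalence_on_random_series(self, rng):
        """1,000 random series, lengths 3-50: implementation matches the
        brute-force formula to 1e-12."""
        worst = 0.0
        for _ in range(1000):
            n = int(rng.integers(3, 51))
            x = rng.uniform(0, 10, n)
            y = rng.uniform(0, 10, n)
            worst = max(worst, abs(pearson_r(x, y) - pearson_brute(x, y)))
        assert worst < 1e-12

    def test_zero_variance_raises_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            pearson_r([1, 2], [3, 4])

    @given(
        a=st.floats(min_value=0.01, max_value=1e3),
        b=st.floats(min_value=0.0, max_value=100.0),
    )
    def test_affine_invariance(self, a, b):
        x = [1.0, 5.0, 2.0, 9.0]
        y = [2.0, 3.0, 1.0, 8.0]
        r0 = pearson_r(x, y)
        r1 = pearson_r([a * v + b for v in x], y)
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestFoldChange:
    @pytest.mark.parametrize(
        "values,pseudo,expected",
        [([2, 10], 0.0, 5.0), ([7, 7, 7], 0.0, 1.0), ([0, 9], 1.0, 10.0)],
    )
    def test_arithmetic(self, values, pseudo, expected):
        assert fold_change(values, pseudo) == pytest.approx(expected)

    def test_all_zero_without_pseudocount_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            fold_change([0.0, 0.0], 0.0)


def _pair(band, orth, samples=None):
    samples = samples or PANEL[: len(band)]
    return SeriesPair(np.asarray(band, float), np.asarray(orth, float), samples)


class TestOrthogonalValidate:
    def test_tracking_band_is_enhanced(self, config):
        orth = [1, 2, 4, 8, 16, 32, 64, 128]
        band = [v * 10 for v in orth]
        res = orthogonal_validate(_pair(band, orth), config)
        assert res.status is PillarStatus.ENHANCED
        assert res.metrics["pearson_r"] == pytest.approx(1.0)

    def test_uncorrelated_band_same_size_not_validated(self, config, rng):
        """The second-antibody situation: a band of the right size whose
        intensities ignore the orthogonal series."""
        orth = [1, 2, 4, 8, 16, 32, 64, 128]
        band = list(rng.permutation([5, 1, 3, 2, 8, 1, 2, 1]))
        res = orthogonal_validate(_pair(band, orth), config)
        assert res.status in (PillarStatus.NOT_VALIDATED, PillarStatus.ENHANCED)
        # deterministic variant: anti-correlated band
        res = orthogonal_validate(_pair(orth[::-1], orth), config)
        assert res.status is PillarStatus.NOT_VALIDATED

    def test_low_variability_gate_is_uncertain(self, config):
        orth = [10, 11, 12, 13, 10.5, 11.5, 12.5, 13.5]  # fold < 5
        band = orth  # even a perfectly tracking band cannot validate
        res = orthogonal_validate(_pair(band, orth), config)
        assert res.status is PillarStatus.UNCERTAIN
        assert res.metrics["fold_change"] < config.fold_min

    def test_r_exactly_at_threshold_fails_strictly(self, config):
        """r = 0.5 exactly does not exceed the cut-off: not validated."""
        band = [1.0, 3.0, 2.0]
        orth = [1.0, 2.0, 3.0]
        # fold_min lowered so the variability gate admits this tiny series
        # and the correlation threshold itself is what decides
        cfg = PillarConfig(pseudocount=0.0, fold_min=1.2)
        res = orthogonal_validate(_pair(band, orth, ["a", "b", "c"]), cfg)
        assert res.metrics["pearson_r"] == 0.5
        assert res.status is PillarStatus.NOT_VALIDATED

    def test_fold_exactly_at_threshold_passes_gate(self):
        """Fold-change of exactly 5 is not 'less than fivefold': the gate
        admits the antibody to the correlation test."""
        cfg = PillarConfig(pseudocount=0.0)
        orth = [1.0, 2.0, 5.0]
        res = orthogonal_validate(_pair([1.0, 2.0, 5.0], orth, ["a", "b", "c"]), cfg)
        assert res.metrics["fold_change"] == 5.0
        assert res.status is PillarStatus.ENHANCED

    def test_missing_samples_dropped_pairwise(self, config):
        band = [1, 2, 4, np.nan, 16, 32, 64, 128]
        orth = [1, 2, 4, 8, 16, 32, np.nan, 128]
        res = orthogonal_validate(_pair(band, orth), config)
        assert res.metrics["n_samples"] == 6
        assert res.status is PillarStatus.ENHANCED

    def test_fewer_than_three_shared_is_uncertain(self, config):
        band = [1, np.nan, np.nan, 8]
        orth = [1, 2, 4, 8]
        res = orthogonal_validate(_pair(band, orth, PANEL[:4]), config)
        assert res.status is PillarStatus.UNCERTAIN

    def test_scale_invariance_of_status(self, config, rng):
        """Multiplying either series by a positive constant never changes
        the verdict (correlation and fold-change are scale-free)."""
        cfg = PillarConfig(pseudocount=0.0)
        for _ in range(20):
            band = rng.uniform(0.1, 10, 8)
            orth = rng.uniform(0.1, 100, 8)
            base = orthogonal_validate(_pair(band, orth), cfg).status
            for k in (1e-3, 7.3, 1e4):
                assert orthogonal_validate(_pair(band * k, orth), cfg).status is base
                assert orthogonal_validate(_pair(band, orth * k), cfg).status is base

    def test_threshold_monotonicity(self, rng):
        """Raising r_min never promotes to enhanced; lowering fold_min never
        demotes enhanced to uncertain."""
        for _ in range(30):
            band = rng.uniform(0.1, 10, 8)
            orth = rng.uniform(0.1, 100, 8)
            lo = orthogonal_validate(_pair(band, orth), PillarConfig(r_min=0.3)).status
            hi = orthogonal_validate(_pair(band, orth), PillarConfig(r_min=0.7)).status
            if lo is PillarStatus.NOT_VALIDATED:
                assert hi is not PillarStatus.ENHANCED
            strict = orthogonal_validate(_pair(band, orth), PillarConfig(fold_min=8.0)).status
            lax = orthogonal_validate(_pair(band, orth), PillarConfig(fold_min=3.0)).status
            if strict is PillarStatus.ENHANCED:
                assert lax is not PillarStatus.UNCERTAIN


class TestTwoLineValidate:
    def two(self, band, orth):
        return SeriesPair(np.array(band, float), np.array(orth, float), ["RT4", "U-251"])

    def test_fivefold_concordant_enhanced(self, config):
        res = two_line_validate(self.two([0.9, 0.1], [100, 10]), False, config)
        assert res.status is PillarStatus.ENHANCED

    def test_trend_plus_size_path(self, config):
        res = two_line_validate(self.two([0.9, 0.4], [30, 10]), True, config)
        assert res.status is PillarStatus.ENHANCED
        assert "size" in res.note

    def test_low_fold_without_size_support_uncertain(self, config):
        res = two_line_validate(self.two([0.9, 0.4], [30, 10]), False, config)
        assert res.status is PillarStatus.UNCERTAIN

    def test_discordant_ordering_not_validated(self, config):
        res = two_line_validate(self.two([0.1, 0.9], [100, 10]), False, config)
        assert res.status is PillarStatus.NOT_VALIDATED

    def test_no_band_anywhere_uncertain(self, config):
        res = two_line_validate(self.two([0.0, 0.0], [100, 10]), True, config)
        assert res.status is PillarStatus.UNCERTAIN


def _lanes(ab, mws_by_sample, intensities):
    return [
        LaneProfile(ab, s, [Band(mw, inten)])
        for (s, mw), inten in zip(mws_by_sample.items(), intensities)
    ]


class TestIndependentValidate:
    AB_A = AntibodyRecord("abA", "HNMT", (10, 50))
    AB_B = AntibodyRecord("abB", "HNMT", (60, 120))

    def test_identical_patterns_enhanced(self, config):
        mws = {s: 33.0 for s in FIVE_SAMPLES}
        la = _lanes("abA", mws, [5, 1, 0.5, 3, 2])
        lb = _lanes("abB", mws, [10, 2, 1, 6, 4])
        res = independent_validate(la, lb, self.AB_A, self.AB_B, config)
        assert res.status is PillarStatus.ENHANCED

    def test_overlapping_epitopes_uncertain(self, config):
        ab_b = AntibodyRecord("abB", "HNMT", (40, 80))
        mws = {s: 33.0 for s in FIVE_SAMPLES}
        la = _lanes("abA", mws, [5, 1, 0.5, 3, 2])
        lb = _lanes("abB", mws, [10, 2, 1, 6, 4])
        res = independent_validate(la, lb, self.AB_A, ab_b, config)
        assert res.status is PillarStatus.UNCERTAIN
        assert "overlap" in res.note

    def test_discordant_partner_flagged_uncertain(self, config):
        """A partner staining a band 20 kDa away in one tissue marks the
        pair uncertain, pointing at the partner's non-specific staining."""
        mws_a = {s: 33.0 for s in FIVE_SAMPLES}
        mws_b = dict(mws_a, liver=53.0)
        la = _lanes("abA", mws_a, [5, 1, 0.5, 3, 2])
        lb = _lanes("abB", mws_b, [10, 2, 1, 6, 4])
        res = independent_validate(la, lb, self.AB_A, self.AB_B, config)
        assert res.status is PillarStatus.UNCERTAIN
        assert res.metrics["discordant_partner_flag"] == 1.0
        assert "liver" in res.note

    def test_two_shared_detections_use_ordering(self, config):
        mws = {"RT4": 33.0, "U-251": 33.0}
        la = _lanes("abA", mws, [5, 1])
        lb = _lanes("abB", mws, [8, 2])
        res = independent_validate(la, lb, self.AB_A, self.AB_B, config)
        assert res.status is PillarStatus.ENHANCED

    def test_different_targets_usage_error(self, config):
        other = AntibodyRecord("abB", "AASS", (60, 120))
        with pytest.raises(UsageError):
            independent_validate([], [], self.AB_A, other, config)


class TestGeneticValidate:
    @pytest.mark.parametrize(
        "kds,expected",
        [
            ((0.70, 0.95), PillarStatus.ENHANCED),   # 30% reduction
            ((0.80, 0.85), PillarStatus.UNCERTAIN),  # 20% reduction
            ((0.75,), PillarStatus.UNCERTAIN),       # exactly 25%: strict
        ],
    )
    def test_quarter_reduction_rule(self, kds, expected, config):
        res = genetic_validate(1.0, list(kds), config)
        assert res.status is expected

    def test_verified_knockdown_maps_failure_to_not_validated(self, config):
        res = genetic_validate(1.0, [0.95], config, kd_verified=True)
        assert res.status is PillarStatus.NOT_VALIDATED

    def test_nonpositive_control_rejected(self, config):
        with pytest.raises(DataValueError):
            genetic_validate(0.0, [0.5], config)


class TestRecombinantValidate:
    def test_band_only_under_expression_enhanced(self, config):
        ctrl = LaneProfile("ab", "control", [])
        oe = LaneProfile("ab", "oe", [Band(50, 1000)])
        res = recombinant_validate(ctrl, oe, True, config)
        assert res.status is PillarStatus.ENHANCED

    def test_no_expression_uncertain(self, config):
        res = recombinant_validate(
            LaneProfile("ab", "control", []), LaneProfile("ab", "oe", []), False, config
        )
        assert res.status is PillarStatus.UNCERTAIN

    def test_equal_bands_not_validated(self, config):
        ctrl = LaneProfile("ab", "control", [Band(50, 100)])
        oe = LaneProfile("ab", "oe", [Band(50, 100)])
        res = recombinant_validate(ctrl, oe, True, config)
        assert res.status is PillarStatus.NOT_VALIDATED

    def test_no_band_despite_expression_not_validated(self, config):
        ctrl = LaneProfile("ab", "control", [Band(50, 100)])
        res = recombinant_validate(ctrl, LaneProfile("ab", "oe", []), True, config)
        assert res.status is PillarStatus.NOT_VALIDATED


class TestAggregation:
    def test_counts_and_missing_pillars(self):
        rep = aggregate(
            [
                PillarResult(Pillar.ORTHOGONAL, PillarStatus.ENHANCED),
                PillarResult(Pillar.CAPTURE_MS, PillarStatus.ENHANCED),
                PillarResult(Pillar.GENETIC, PillarStatus.UNCERTAIN),
            ],
            antibody_id="ab1",
        )
        assert rep.n_enhanced == 2
        assert rep.status_of(Pillar.RECOMBINANT) is PillarStatus.NOT_DONE
        assert len(rep.pillar_results) == 5

    def test_empty_input_all_not_done(self):
        rep = aggregate([])
        assert rep.n_enhanced == 0
        assert all(r.status is PillarStatus.NOT_DONE for r in rep.pillar_results)

    def test_duplicate_pillar_rejected(self):
        with pytest.raises(UsageError):
            aggregate(
                [
                    PillarResult(Pillar.GENETIC, PillarStatus.ENHANCED),
                    PillarResult(Pillar.GENETIC, PillarStatus.ENHANCED),
                ]
            )

    def test_summary_counts(self):
        reports = []
        for k in (1, 2, 3):
            results = [
                PillarResult(p, PillarStatus.ENHANCED)
                for p in list(Pillar)[:k]
            ]
            reports.append(aggregate(results, antibody_id=f"ab{k}"))
        s = summarize_cohort(reports)
        assert s["validated_ge"][1] == 3
        assert s["validated_ge"][2] == 2
        assert s["validated_ge"][3] == 1

    def test_summary_matches_brute_recount(self, rng):
        """Random cohort: tail counts and per-pillar counts agree with an
        independent recount, and tails are non-increasing in k."""
        statuses = list(PillarStatus)
        reports = []
        for i in range(300):
            results = [
                PillarResult(p, statuses[rng.integers(0, 4)]) for p in Pillar
            ]
            reports.append(ValidationReport(f"ab{i}", results))
        s = summarize_cohort(reports)
        for k in range(1, 6):
            brute = sum(
                1
                for r in reports
                if sum(pr.status is PillarStatus.ENHANCED for pr in r.pillar_results) >= k
            )
            assert s["validated_ge"][k] == brute
        for p in Pillar:
            brute = sum(
                1
                for r in reports
                for pr in r.pillar_results
                if pr.pillar is p and pr.status is PillarStatus.ENHANCED
            )
            assert s["per_pillar_enhanced"][p.value] == brute
        tails = [s["validated_ge"][k] for k in range(1, 6)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))
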