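"""Agreement/reliability battery: normality gate, paired tests, ICC, SEM/MDC,
Bland-Altman, interpretation bands, and the pingouin cross-check for ICC."""
import math

import numpy as np
import pytest

from hrvguide import (
    InsufficientDataError,
    PairedSample,
    UndefinedStatisticError,
    ValidationError,
    bland_altman,
    compare,
    icc_reliability,
    mdc_from_sem_percent,
    paired_comparison,
    pearson_with_band,
    reliability,
    sem_and_mdc,
    shapiro_wilk_gate,
)
from hrvguide.agreement_stats import (
    MDC_FACTOR,
    interpret_cohens_d,
    interpret_icc,
    interpret_pearson_r,
)


class TestShapiroGate:
    def test_normal_sample_passes(self):
        rng = np.random.default_rng(8)
        passes = sum(shapiro_wilk_gate(rng.normal(0, 1, 20))[0] for _ in range(100))
        assert passes >= 90

    def test_bimodal_sample_fails(self):
        rng = np.random.default_rng(9)
        values = np.concatenate([rng.normal(-10, 0.1, 10), rng.normal(10, 0.1, 10)])
        normal, w, p = shapiro_wilk_gate(values)
        assert not normal

    @pytest.mark.parametrize("n", [2, 50, 80])
    def test_sample_size_outside_range_rejected(self, n):
        with pytest.raises(ValidationError):
            shapiro_wilk_gate(np.zeros(n) + np.arange(n))


class TestPairedComparison:
    def test_identical_vectors(self):
        x = np.array([3.9, 4.0, 4.1, 4.2])
        rep = paired_comparison(PairedSample(x, x.copy()), n_comparisons=3)
        assert rep.mean_diff == 0.0
        assert rep.cohens_d == 0.0
        assert rep.p_value == 1.0

    def test_mean_difference_from_group_means(self):
        # device comparison scale: groups with means 3.995 and 3.964
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.5, 20)
        x = x - x.mean() + 3.995
        y = x - 0.031
        rep = paired_comparison(PairedSample(x, y))
        assert rep.mean_diff == pytest.approx(0.031, abs=1e-12)

    def test_constant_offset_gives_infinite_d_sentinel(self):
        x = np.array([4.0, 4.2, 4.4])
        rep = paired_comparison(PairedSample(x + 0.5, x))
        assert math.isinf(rep.cohens_d) and rep.cohens_d > 0
        assert rep.effect_ci == (0.5, 0.5)
        assert rep.warnings

    def test_bonferroni_scales_and_caps(self):
        rng = np.random.default_rng(4)
        x = rng.normal(4, 0.5, 15)
        y = x + rng.normal(0.0, 0.3, 15)
        p1 = paired_comparison(PairedSample(x, y), 1).p_value
        p4 = paired_comparison(PairedSample(x, y), 4).p_value
        assert p4 == pytest.approx(min(1.0, 4 * p1))

    def test_d_uses_difference_sd(self):
        rng = np.random.default_rng(6)
        x = rng.normal(4, 0.6, 25)
        y = x - 0.1 + rng.normal(0, 0.2, 25)
        rep = paired_comparison(PairedSample(x, y))
        d = x - y
        assert rep.cohens_d == pytest.approx(d.mean() / d.std(ddof=1))

    def test_fewer_than_three_subjects_rejected(self):
        with pytest.raises(InsufficientDataError):
            PairedSample(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson_with_band(PairedSample(2 * x + 1, x))
        assert res.r == pytest.approx(1.0)
        assert res.interpretation == "almost_perfect"

    def test_negative_relation_banded_by_magnitude(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson_with_band(PairedSample(-x, x))
        assert res.r == pytest.approx(-1.0)
        assert res.interpretation == "almost_perfect"

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_with_band(PairedSample(np.ones(5), np.arange(5.0)))


class TestInterpretationBands:
    @pytest.mark.parametrize(
        "d, band",
        [
            (0.0, "trivial"),
            (0.19, "trivial"),
            (0.20, "small"),
            (0.49, "small"),
            (0.50, "moderate"),
            (0.79, "moderate"),
            (0.80, "large"),
            (-0.615, "moderate"),
        ],
    )
    def test_cohens_d_bands(self, d, band):
        assert interpret_cohens_d(d) == band

    @pytest.mark.parametrize(
        "r, band",
        [
            (0.05, "trivial"),
            (0.10, "small"),
            (0.29, "small"),
            (0.30, "moderate"),
            (0.49, "moderate"),
            (0.50, "high"),
            (0.69, "high"),
            (0.70, "very_high"),
            (0.85, "very_high"),
            (0.89, "very_high"),
            (0.90, "almost_perfect"),
            (0.99, "almost_perfect"),
        ],
    )
    def test_pearson_bands(self, r, band):
        assert interpret_pearson_r(r) == band

    @pytest.mark.parametrize(
        "icc, band",
        [
            (0.50, "poor_to_moderate"),
            (0.74, "poor_to_moderate"),
            (0.75, "good"),
            (0.80, "good"),
            (0.89, "good"),
            (0.90, "excellent"),
            (0.93, "excellent"),
        ],
    )
    def test_icc_bands(self, icc, band):
        assert interpret_icc(icc) == band


class TestICC:
    def test_identical_trials_give_unity(self):
        x = np.array([3.5, 4.0, 4.5, 5.0, 3.8])
        icc, ci, band = icc_reliability(x, x.copy())
        assert icc == 1.0
        assert ci == (1.0, 1.0)
        assert band == "excellent"

    def test_overwhelming_noise_gives_near_zero(self):
        rng = np.random.default_rng(21)
        x = rng.normal(4.0, 0.1, 30)
        y = x + rng.normal(0, 5.0, 30)  # noise SD >> subject SD
        icc, ci, band = icc_reliability(x, y)
        assert icc < 0.2
        assert band == "poor_to_moderate"

    def test_matches_pingouin_absolute_agreement(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        x = rng.normal(4, 0.6, 20)
        y = x + rng.normal(0, 0.2, 20)
        icc, ci, _ = icc_reliability(x, y, ci_level=0.95)
        frame = pd.DataFrame(
            {
                "subject": list(range(20)) * 2,
                "rater": ["a"] * 20 + ["b"] * 20,
                "score": np.concatenate([x, y]),
            }
        )
        ref = pg.intraclass_corr(frame, targets="subject", raters="rater", ratings="score")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0] if (ref["Type"] == "ICC(A,1)").any() else ref[ref["Type"] == "ICC2"].iloc[0]
        assert icc == pytest.approx(float(row["ICC"]), abs=1e-9)
        ref_ci = row["CI95"] if "CI95" in row else row["CI95%"]
        assert ci[0] == pytest.approx(float(ref_ci[0]), abs=0.01)
        assert ci[1] == pytest.approx(float(ref_ci[1]), abs=0.01)

    def test_no_between_subject_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc_reliability(np.full(5, 4.0), np.full(5, 4.0))

    def test_variance_components_oracle(self):
        # simulated two-way design with known variance components:
        # ICC(A,1) ~ s2_subj / (s2_subj + s2_trial + s2_err)
        rng = np.random.default_rng(31)
        s_subj, s_err = 0.5, 0.2
        n = 4000
        subj = rng.normal(0, s_subj, n)
        x = subj + rng.normal(0, s_err, n)
        y = subj + rng.normal(0, s_err, n)
        icc, _, _ = icc_reliability(x, y)
        expected = s_subj**2 / (s_subj**2 + s_err**2)
        assert icc == pytest.approx(expected, abs=0.03)


class TestSemMdc:
    @pytest.mark.parametrize(
        "sem_pct, mean, mdc",
        [(4.51, 3.995, 0.50), (2.11, 3.947, 0.23)],
    )
    def test_printed_sem_percent_reproduces_mdc(self, sem_pct, mean, mdc):
        sem_abs, mdc_abs = mdc_from_sem_percent(sem_pct, mean)
        assert round(mdc_abs, 2) == mdc

    def test_perfect_reliability_zeroes_sem_and_mdc(self):
        x = np.array([3.5, 4.0, 4.5])
        sem_abs, sem_pct, mdc_abs = sem_and_mdc(x, x, 1.0, 4.0)
        assert sem_abs == 0.0 and sem_pct == 0.0 and mdc_abs == 0.0

    def test_mdc_to_sem_ratio_is_fixed(self):
        rng = np.random.default_rng(2)
        x = rng.normal(4, 0.5, 15)
        y = x + rng.normal(0, 0.2, 15)
        sem_abs, _, mdc_abs = sem_and_mdc(x, y, 0.9, 4.0)
        assert mdc_abs / sem_abs == pytest.approx(MDC_FACTOR)
        assert MDC_FACTOR == pytest.approx(2.772, abs=5e-4)

    def test_non_positive_group_mean_rejected(self):
        with pytest.raises(ValidationError):
            sem_and_mdc(np.ones(3), np.ones(3) + 0.1, 0.9, 0.0)


class TestBlandAltman:
    def test_identical_vectors(self):
        x = np.array([4.0, 4.1, 4.2])
        ba = bland_altman(PairedSample(x, x.copy()))
        assert (ba.bias, ba.loa_lower, ba.loa_upper) == (0.0, 0.0, 0.0)

    def test_pure_offset_has_zero_width(self):
        x = np.array([4.0, 4.1, 4.2])
        ba = bland_altman(PairedSample(x + 0.1, x))
        assert ba.bias == pytest.approx(0.1)
        assert ba.loa_lower == pytest.approx(0.1)
        assert ba.loa_upper == pytest.approx(0.1)

    def test_loa_halfwidth_matches_normal_quantile(self):
        rng = np.random.default_rng(77)
        x = rng.normal(4.0, 0.6, 2000)
        y = x + rng.normal(0, 0.05, 2000)
        ba = bland_altman(PairedSample(x, y))
        halfwidth = (ba.loa_upper - ba.loa_lower) / 2
        assert halfwidth == pytest.approx(1.96 * 0.05, rel=0.05)

    def test_loa_symmetric_about_bias(self):
        rng = np.random.default_rng(12)
        x = rng.normal(4, 0.5, 40)
        y = x + rng.normal(0.05, 0.1, 40)
        ba = bland_altman(PairedSample(x, y))
        assert ba.loa_upper - ba.bias == pytest.approx(ba.bias - ba.loa_lower)


class TestSymmetry:
    def test_swapping_conditions_negates_signed_stats(self):
        rng = np.random.default_rng(15)
        x = rng.normal(4, 0.5, 20)
        y = x + rng.normal(0.1, 0.15, 20)
        sample = PairedSample(x, y)
        fwd = compare(sample)
        rev = compare(sample.swapped())
        assert rev.mean_diff == pytest.approx(-fwd.mean_diff)
        assert rev.bias == pytest.approx(-fwd.bias)
        assert rev.cohens_d == pytest.approx(-fwd.cohens_d)
        assert abs(rev.pearson_r) == pytest.approx(abs(fwd.pearson_r))
        assert rev.p_value == pytest.approx(fwd.p_value)

    def test_swapping_trials_preserves_reliability(self):
        rng = np.random.default_rng(16)
        x = rng.normal(4, 0.5, 20)
        y = x + rng.normal(0, 0.2, 20)
        fwd = reliability(x, y)
        rev = reliability(y, x)
        assert rev.icc == pytest.approx(fwd.icc)
        assert rev.sem_abs == pytest.approx(fwd.sem_abs)
        assert rev.mdc_abs == pytest.approx(fwd.mdc_abs)


class TestParameterRecovery:
    def test_bias_and_loa_recover_planted_values(self):
        rng = np.random.default_rng(99)
        planted_bias, sigma = 0.08, 0.04
        x = rng.normal(4, 0.6, 2000)
        y = x - planted_bias + rng.normal(0, sigma, 2000)
        ba = bland_altman(PairedSample(x, y))
        assert ba.bias == pytest.approx(planted_bias, abs=3 * sigma / math.sqrt(2000))
        assert (ba.loa_upper - ba.bias) == pytest.approx(1.96 * sigma, rel=0.1)
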