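import math

import numpy as np
import pytest

from methbench.core import MDRE, MSRE
from methbench.qpcr import (
    UNDETECTED,
    StandardCurve,
    fit_standard_curve,
    interpolate_copies,
    mean_cq,
    methylight_qpcr_percent,
    re_qpcr_percent,
)

PERFECT_SLOPE = -1.0 / math.log10(2.0)


class TestMeanCq:
    def test_mean_and_sd_over_detected_wells(self):
        s = mean_cq([30.0, 30.2, 30.4])
        assert s.mean == pytest.approx(30.2)
        assert s.sd == pytest.approx(0.2)
        assert s.n_detected == 3

    def test_all_undetected_propagates(self):
        s = mean_cq([UNDETECTED] * 3)
        assert s.mean is UNDETECTED and s.n_detected == 0

    def test_partial_detection_uses_detected_only(self):
        s = mean_cq([30.0, UNDETECTED])
        assert s.mean == pytest.approx(30.0)
        assert s.n_detected == 1 and s.n_total == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_cq([])


class TestReQpcrPercent:
    def test_control_against_itself_is_fully_methylated_for_msre(self):
        wells = {"digest": [30.0, 30.1], "mock": [30.0, 30.1]}
        res = re_qpcr_percent(
            wells["digest"], wells["mock"], wells["digest"], wells["mock"], MSRE
        )
        assert res.delta_delta_cq == pytest.approx(0.0)
        assert res.percent == pytest.approx(100.0)

    def test_one_cycle_delay_halves_msre_estimate(self):
        # sample digest is one cycle later than its mock -> ddCq = -1
        res = re_qpcr_percent([31.0], [30.0], [30.0], [30.0], MSRE)
        assert res.percent == pytest.approx(50.0)

    def test_mdre_closed_form(self):
        # ddCq = -2 -> surviving unmethylated quarter -> 75% methylated
        res = re_qpcr_percent([32.0], [30.0], [30.0], [30.0], MDRE)
        assert res.delta_delta_cq == pytest.approx(-2.0)
        assert res.percent == pytest.approx(75.0)

    def test_undetected_digest_means_complete_digestion(self):
        res = re_qpcr_percent([UNDETECTED], [30.0], [30.0], [30.0], MSRE)
        assert res.percent == 0.0
        res = re_qpcr_percent([UNDETECTED], [30.0], [30.0], [30.0], MDRE)
        assert res.percent == 100.0

    def test_undetected_control_mock_raises(self):
        with pytest.raises(ValueError):
            re_qpcr_percent([30.0], [30.0], [30.0], [UNDETECTED], MSRE)

    def test_msre_mdre_complementarity_noiseless(self):
        # perfect enzymes, no noise: MSRE and MDRE estimates of the same
        # sample agree for every panel fraction
        curve = StandardCurve(PERFECT_SLOPE, 40.0, 1.0)
        copies = 1515

        def cq(c):
            return [curve.intercept + curve.slope * math.log10(c)] if c > 0 else [UNDETECTED]

        for f in (1.0, 0.9, 0.75, 0.5, 0.25, 0.1):
            msre = re_qpcr_percent(
                cq(copies * f), cq(copies), cq(copies * 1.0), cq(copies), MSRE
            ).percent
            mdre = re_qpcr_percent(
                cq(copies * (1 - f)) if f < 1 else [UNDETECTED],
                cq(copies), cq(copies * 1.0), cq(copies), MDRE,
            ).percent
            assert msre + (100.0 - mdre) - 100.0 == pytest.approx(0.0, abs=1e-9)

    def test_monte_carlo_recovery_within_propagated_noise(self, rng):
        # sigma = 0.2 over the panel, triplicate wells: the mean estimate
        # within each enzyme's optimal range stays within 3x the
        # propagated sigma of the ddCq chain
        sigma = 0.2
        curve = StandardCurve(PERFECT_SLOPE, 40.0, 1.0)
        copies = 1515
        n_rep = 200
        sd_ddcq = sigma * math.sqrt(4.0 / 3.0)  # four means of 3 wells

        def wells(c):
            if c <= 0:
                return [UNDETECTED] * 3
            base = curve.intercept + curve.slope * math.log10(c)
            return list(base + rng.normal(0, sigma, 3))

        for f in (0.1, 0.25, 0.5):
            ests = [
                re_qpcr_percent(
                    wells(copies * f), wells(copies),
                    wells(copies), wells(copies), MSRE,
                ).percent
                for _ in range(n_rep)
            ]
            # multiplicative noise: 3 sigma band on the percent scale
            band = 100.0 * f * (2.0 ** (3 * sd_ddcq) - 1.0)
            assert abs(np.mean(ests) - 100.0 * f) < band

    def test_ten_percent_step_near_saturation_is_below_noise_floor(self):
        # the Cq difference between 90% and 100% methylated templates is
        # ~0.15 cycles, smaller than the propagated technical noise at
        # sigma = 0.2 -- the reason RE assays cannot resolve it
        effect = abs(math.log2(0.9))
        propagated = 0.2 * math.sqrt(4.0 / 3.0)
        assert 0.14 < effect < 0.2
        assert propagated > effect


class TestStandardCurve:
    LEVELS = [7575.0, 1515.0, 303.0, 60.6, 12.1]

    def _exact_points(self):
        return [(c, 40.0 + PERFECT_SLOPE * math.log10(c)) for c in self.LEVELS]

    def test_noiseless_recovery(self):
        curve = fit_standard_curve(self._exact_points())
        assert curve.slope == pytest.approx(PERFECT_SLOPE, abs=1e-9)
        assert curve.intercept == pytest.approx(40.0, abs=1e-9)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0)

    def test_shifted_level_matches_closed_form_least_squares(self):
        points = self._exact_points()
        points[2] = (points[2][0], points[2][1] + 0.5)
        curve = fit_standard_curve(points)
        # independent closed-form OLS oracle
        x = np.log10([p[0] for p in points])
        y = np.array([p[1] for p in points])
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        assert curve.slope == pytest.approx(slope, abs=1e-12)
        assert curve.intercept == pytest.approx(intercept, abs=1e-12)
        assert curve.r_squared < 1.0

    def test_constant_cq_is_degenerate(self):
        with pytest.raises(ValueError):
            fit_standard_curve([(c, 30.0) for c in self.LEVELS])

    def test_too_few_levels_or_bad_copies_rejected(self):
        with pytest.raises(ValueError):
            fit_standard_curve(self._exact_points()[:2])
        with pytest.raises(ValueError):
            fit_standard_curve([(0.0, 40.0), (10.0, 36.0), (100.0, 33.0)])

    def test_replicate_wells_averaged_per_level(self):
        points = [(c, [cq - 0.1, cq + 0.1]) for c, cq in self._exact_points()]
        curve = fit_standard_curve(points)
        assert curve.slope == pytest.approx(PERFECT_SLOPE, abs=1e-9)

    @pytest.mark.parametrize(
        "cq, copies",
        [(40.0, 1.0), (30.0, 10.0 ** (10.0 / 3.3219))],
    )
    def test_interpolation(self, cq, copies):
        curve = StandardCurve(-3.3219, 40.0, 1.0)
        value, detected = interpolate_copies(curve, cq)
        assert detected and value == pytest.approx(copies, rel=1e-6)

    def test_interpolation_of_undetected_flags_zero(self):
        curve = StandardCurve(-3.3219, 40.0, 1.0)
        value, detected = interpolate_copies(curve, UNDETECTED)
        assert value == 0.0 and not detected

    def test_fit_interpolate_round_trip(self):
        curve = fit_standard_curve(self._exact_points())
        for c in self.LEVELS:
            cq = 40.0 + PERFECT_SLOPE * math.log10(c)
            value, _ = interpolate_copies(curve, cq)
            assert value == pytest.approx(c, rel=1e-6)


class TestMethylightPercent:
    @pytest.mark.parametrize(
        "p14, col, ref, expected",
        [(500.0, 1000.0, 0.5, 100.0), (0.0, 1000.0, 0.5, 0.0),
         (250.0, 1000.0, 0.5, 50.0)],
    )
    def test_normalisation_chain(self, p14, col, ref, expected):
        assert methylight_qpcr_percent(p14, col, ref) == pytest.approx(expected)

    def test_absent_reference_signal_raises(self):
        with pytest.raises(ValueError):
            methylight_qpcr_percent(100.0, 0.0, 0.5)
        with pytest.raises(ValueError):
            methylight_qpcr_percent(100.0, 100.0, 0.0)
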