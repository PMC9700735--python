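import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nucleoforce.fractions import (
    ArrheniusFit,
    arrhenius_probability,
    clopper_pearson,
    delta_g,
    difference_curve,
    fit_arrhenius,
    tetrasome_correct,
    unwrapped_fraction,
)
from tests.conftest import FIT_WITH, FIT_WITHOUT


class TestUnwrappedFraction:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(202, 421, 0.480), (34, 65, 0.523), (0, 50, 0.0)],
    )
    def test_measured_fractions(self, k, n, expected):
        est = unwrapped_fraction(k, n)
        assert est.alpha == pytest.approx(expected, abs=0.001)
        assert est.ci_low <= est.alpha <= est.ci_high

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            unwrapped_fraction(0, 0)


class TestClopperPearson:
    def test_closed_form_extremes(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-9)
        lo2, hi2 = clopper_pearson(10, 10)
        assert (lo2, hi2) == pytest.approx((1 - hi, 1.0), abs=1e-9)

    def test_half_interval(self):
        assert clopper_pearson(5, 10) == pytest.approx((0.187, 0.813), abs=0.001)

    def test_matches_brute_force_tail_inversion(self):
        """The beta-quantile interval equals direct binomial tail search."""
        p_grid = np.linspace(1e-6, 1 - 1e-6, 20001)
        for n in range(1, 31):
            for k in range(n + 1):
                lo, hi = clopper_pearson(k, n)
                # smallest p with P(X >= k) >= 0.025; largest with P(X <= k) >= 0.025
                if k > 0:
                    upper_tail = 1 - stats.binom.cdf(k - 1, n, p_grid)
                    brute_lo = p_grid[np.argmax(upper_tail >= 0.025)]
                    assert lo == pytest.approx(brute_lo, abs=1e-3)
                if k < n:
                    lower_tail = stats.binom.cdf(k, n, p_grid)
                    brute_hi = p_grid[len(p_grid) - 1 - np.argmax(lower_tail[::-1] >= 0.025)]
                    assert hi == pytest.approx(brute_hi, abs=1e-3)

    def test_coverage_at_nominal_level(self):
        """Exact intervals cover the true p at >= 95% for n <= 30."""
        for n in (5, 12, 30):
            for p in (0.1, 0.35, 0.5, 0.8):
                cover = 0.0
                for k in range(n + 1):
                    lo, hi = clopper_pearson(k, n)
                    if lo <= p <= hi:
                        cover += stats.binom.pmf(k, n, p)
                assert cover >= 0.95

    @given(st.integers(0, 30), st.integers(1, 30))
    @settings(max_examples=60, deadline=None)
    def test_interval_contains_point_estimate(self, k, n):
        k = min(k, n)
        lo, hi = clopper_pearson(k, n)
        assert lo <= k / n <= hi


class TestTetrasomeCorrection:
    @pytest.mark.parametrize("alpha,expected", [(0.26, 0.0), (1.0, 1.0), (0.63, 0.50)])
    def test_formula(self, alpha, expected):
        assert tetrasome_correct(alpha) == pytest.approx(expected)

    def test_clipped_below_tetrasome_fraction(self):
        assert tetrasome_correct(0.1) == 0.0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            tetrasome_correct(0.5, tetrasome_fraction=1.0)

    @given(st.floats(0.26, 1.0))
    @settings(max_examples=40, deadline=None)
    def test_corrected_never_exceeds_raw(self, alpha):
        assert tetrasome_correct(alpha) <= alpha + 1e-12


class TestArrheniusProbability:
    def test_midpoint_is_half(self):
        assert arrhenius_probability(10.6, FIT_WITHOUT) == pytest.approx(0.5)

    def test_printed_probabilities_at_8p2(self):
        # the force of maximal remodeler effect: ~4% vs ~95% within 10 min
        assert arrhenius_probability(8.2, FIT_WITHOUT) == pytest.approx(0.035, abs=0.002)
        assert arrhenius_probability(8.2, FIT_WITH) == pytest.approx(0.947, abs=0.002)

    def test_strictly_increasing(self):
        f = np.linspace(0.1, 30, 500)
        p = arrhenius_probability(f, FIT_WITHOUT)
        assert np.all(np.diff(p) > 0)


class TestFitArrhenius:
    def test_exact_recovery_on_curve(self):
        forces = [3, 5, 7.5, 10, 12.5, 15]
        n = 10**6
        obs = [
            (F, int(round(arrhenius_probability(F, FIT_WITHOUT) * n)), n)
            for F in forces
        ]
        fit = fit_arrhenius(obs)
        assert fit.f_half == pytest.approx(10.6, rel=1e-3)
        assert fit.delta_x == pytest.approx(5.7, rel=1e-3)

    def test_too_few_forces_rejected(self):
        with pytest.raises(ValueError):
            fit_arrhenius([(5, 2, 10), (10, 8, 10)])

    def test_complete_separation_rejected(self):
        with pytest.raises(ValueError, match="separation"):
            fit_arrhenius([(5, 0, 10), (10, 0, 10), (15, 0, 10)])

    @pytest.mark.parametrize("f_half,dx", [(10.6, 5.7), (5.5, 4.4)])
    def test_f_half_ci_coverage_in_recovery_study(self, f_half, dx):
        """95% CI for F_half covers the generating value in >=90% of replicates."""
        gen = ArrheniusFit(f_half, dx)
        forces = [3, 5, 7.5, 10, 12.5, 15]
        rng = np.random.default_rng(20240 + int(f_half * 10))
        cover = 0
        n_rep = 200
        for _ in range(n_rep):
            obs = [
                (F, int(rng.binomial(60, arrhenius_probability(F, gen))), 60)
                for F in forces
            ]
            fit = fit_arrhenius(obs)
            if abs(fit.f_half - f_half) <= 1.96 * fit.f_half_se:
                cover += 1
        assert cover / n_rep >= 0.90


class TestDeltaG:
    def test_printed_barriers(self):
        assert delta_g(FIT_WITHOUT) == pytest.approx(14.7, abs=0.1)  # "~15 kBT"
        assert delta_g(FIT_WITH) == pytest.approx(5.9, abs=0.1)  # "~6 kBT"

    def test_rescaling_invariance(self):
        # F -> cF with dx -> dx/c leaves the barrier unchanged
        c = 3.7
        scaled = ArrheniusFit(f_half=10.6 * c, delta_x=5.7 / c)
        assert delta_g(scaled) == pytest.approx(delta_g(FIT_WITHOUT), rel=1e-12)


class TestDifferenceCurve:
    def test_peak_and_fwhm_of_printed_fits(self):
        dc = difference_curve(FIT_WITHOUT, FIT_WITH)
        assert dc["peak_force"] == pytest.approx(8.26, abs=0.1)
        assert dc["peak_height"] == pytest.approx(0.91, abs=0.01)
        assert dc["fwhm_low"] == pytest.approx(5.3, abs=0.1)
        assert dc["fwhm_high"] == pytest.approx(10.7, abs=0.1)

    def test_identical_fits_have_no_peak(self):
        with pytest.raises(ValueError, match="no positive peak"):
            difference_curve(FIT_WITHOUT, FIT_WITHOUT)
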