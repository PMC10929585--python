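import numpy as np
import pytest

from calcinet import (
    ActivitySeries,
    classify_stability,
    estimate_landscape,
    estimate_neg_log_density,
    fit_energy_polynomial,
    mean_activity,
    rescale_coefficients,
    sample_landscape_activity,
    standardize,
    unscale_coefficients,
)

# tests use a 1e5-bin grid: coefficient drift versus the default 1e6-bin
# grid is checked explicitly in test_grid_resolution_insensitive
TEST_BINS = 100_000


class TestMeanActivity:
    @pytest.mark.parametrize(
        "binary, expected",
        [
            (np.ones((3, 4)), 1.0),
            (np.zeros((3, 4)), 0.0),
            (np.array([[1, 1], [1, 0], [0, 1], [0, 0]]), 0.5),
        ],
    )
    def test_fraction_active(self, binary, expected):
        series = mean_activity(np.asarray(binary))
        if np.isscalar(expected):
            assert np.all(series.m == expected) or np.allclose(series.m, expected)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            mean_activity(np.array([[0.0, 0.5], [1.0, 1.0]]))


class TestStandardize:
    def test_zero_mean_unit_sd(self):
        series = ActivitySeries(m=np.random.default_rng(0).uniform(0, 1, 500))
        m_prime, _, _ = standardize(series)
        assert abs(m_prime.mean()) < 1e-12
        assert abs(m_prime.std() - 1.0) < 1e-12

    def test_round_trip(self):
        m = np.random.default_rng(1).uniform(0, 1, 200)
        m_prime, mu, sigma = standardize(ActivitySeries(m=m))
        np.testing.assert_allclose(mu + sigma * m_prime, m, atol=1e-12)

    def test_constant_series_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            standardize(ActivitySeries(m=np.full(100, 0.4)))


@pytest.fixture(scope="module")
def normal_sample():
    x = np.random.default_rng(2).standard_normal(50_000)
    return (x - x.mean()) / x.std()


class TestNegLogDensity:
    def test_normal_neg_log_density_at_origin(self, normal_sample):
        grid, nlp, _ = estimate_neg_log_density(normal_sample, n_bins=TEST_BINS)
        at_zero = nlp[np.argmin(np.abs(grid))]
        assert at_zero == pytest.approx(0.5 * np.log(2 * np.pi), abs=0.05)

    def test_density_integrates_to_one(self, normal_sample):
        grid, _, density = estimate_neg_log_density(normal_sample, n_bins=TEST_BINS)
        assert np.trapezoid(density, grid) == pytest.approx(1.0, abs=0.01)

    def test_duplication_invariance_up_to_bandwidth(self, normal_sample):
        # doubling by exact duplication changes only the bandwidth rule:
        # h scales by 2^(-1/5), so the density moves by < 5%
        g1, _, d1 = estimate_neg_log_density(normal_sample, n_bins=TEST_BINS)
        _, _, d2 = estimate_neg_log_density(np.concatenate([normal_sample] * 2), n_bins=TEST_BINS)
        bulk = d1 > 0.05
        assert np.max(np.abs(d2[bulk] - d1[bulk]) / d1[bulk]) < 0.05

    def test_empty_and_tiny_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_neg_log_density(np.array([]))
        with pytest.raises(ValueError):
            estimate_neg_log_density(np.zeros(5))


class TestFitEnergyPolynomial:
    def test_exact_quartic_recovered(self):
        grid = np.linspace(-2.7, 2.7, 2001)
        c_true = np.array([0.7, -0.1, 0.45, 0.02, 0.01])
        nlp = np.polynomial.polynomial.polyval(grid, c_true)
        c_hat = fit_energy_polynomial(grid, nlp, weight_mode="none")
        np.testing.assert_allclose(c_hat, c_true, atol=1e-8)

    def test_standard_normal_curvature(self):
        x = np.random.default_rng(3).standard_normal(50_000)
        x = (x - x.mean()) / x.std()
        grid, nlp, _ = estimate_neg_log_density(x, n_bins=TEST_BINS)
        c = fit_energy_polynomial(grid, nlp)
        assert c[2] == pytest.approx(0.5, abs=0.05)
        assert abs(c[1]) < 0.05 and abs(c[3]) < 0.05
        assert abs(c[4]) < 0.02

    def test_quartic_generator_roundtrip(self):
        c_true = np.array([0.0, 0.1, 0.52, -0.03, 0.0])
        series = sample_landscape_activity(c_true, mu=0.4, sigma=0.07, n_samples=50_000, seed=4)
        landscape = estimate_landscape(series, n_bins=TEST_BINS)
        assert landscape.c[2] == pytest.approx(0.52, abs=0.1)
        assert np.sign(landscape.c[3]) == np.sign(c_true[3])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_energy_polynomial(np.arange(3.0), np.arange(3.0), degree=4)


class TestCoefficientTransforms:
    def test_identity_when_unstandardized(self):
        c = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        np.testing.assert_allclose(unscale_coefficients(c, 0.0, 1.0), c, atol=1e-12)

    def test_hand_expansion(self):
        # ((m - 1)/2)^2 = 0.25 - 0.5 m + 0.25 m^2
        a = unscale_coefficients(np.array([0, 0, 1.0, 0, 0]), mu=1.0, sigma=2.0)
        np.testing.assert_allclose(a, [0.25, -0.5, 0.25, 0, 0], atol=1e-12)

    def test_pointwise_agreement_on_random_coefficients(self):
        rng = np.random.default_rng(5)
        c = rng.normal(size=5)
        mu, sigma = 0.37, 0.81
        a = unscale_coefficients(c, mu, sigma)
        m = rng.uniform(-2, 2, 100)
        lhs = np.polynomial.polynomial.polyval(m, a)
        rhs = np.polynomial.polynomial.polyval((m - mu) / sigma, c)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_rescale_inverts_unscale(self):
        rng = np.random.default_rng(6)
        c = rng.normal(size=5)
        back = rescale_coefficients(unscale_coefficients(c, 0.4, 0.07), 0.4, 0.07)
        np.testing.assert_allclose(back, c, atol=1e-10)

    def test_non_positive_sigma_rejected(self):
        with pytest.raises(ValueError):
            unscale_coefficients(np.ones(5), 0.0, 0.0)


class TestClassifyStability:
    def test_centered_quadratic_bowl_is_stable(self):
        verdict = classify_stability(np.array([0, 0, 1.0, 0, 0]), (-2.0, 2.0))
        assert verdict.stable and verdict.minimum == pytest.approx(0.0, abs=1e-9)

    def test_monotone_decreasing_energy_is_unstable(self):
        verdict = classify_stability(np.array([0, -1.0, 0, 0, 0]), (-2.0, 2.0))
        assert not verdict.stable
        assert verdict.drift_direction == 1  # downhill toward larger m

    def test_double_well_minimum_matches_analytic_wells(self):
        # E = -m^2 + 0.5 m^4 has minima at m = +/-1
        verdict = classify_stability(np.array([0, 0, -1.0, 0, 0.5]), (-2.0, 2.0))
        assert verdict.stable
        assert abs(abs(verdict.minimum) - 1.0) < 1e-9

    def test_minimum_outside_domain_is_unstable(self):
        # bowl centered at 3, domain ends before it
        verdict = classify_stability(np.array([9.0, -6.0, 1.0, 0, 0]), (-2.0, 2.0))
        assert not verdict.stable
        assert verdict.drift_direction == 1

    def test_verdict_invariant_under_rescaling(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            c = rng.normal(size=5) * np.array([1, 1, 1, 0.3, 0.1])
            mu, sigma = rng.uniform(0.2, 0.6), rng.uniform(0.05, 0.2)
            a = unscale_coefficients(c, mu, sigma)
            lo, hi = -2.0, 2.0
            v_scaled = classify_stability(c, (lo, hi))
            v_unscaled = classify_stability(a, (mu + sigma * lo, mu + sigma * hi))
            assert v_scaled.stable == v_unscaled.stable


class TestEndToEnd:
    def test_double_well_density_recovers_well_positions(self):
        c_true = np.array([0, 0, -1.2, 0, 0.6])  # wells at +/-1
        series = sample_landscape_activity(c_true, mu=0.0, sigma=1.0, n_samples=50_000, seed=8)
        m_prime, _, _ = standardize(series)
        grid, nlp, _ = estimate_neg_log_density(m_prime, n_bins=TEST_BINS)
        c_hat = fit_energy_polynomial(grid, nlp)
        # the sampled variable is re-standardized, so wells shrink by its sd
        sd = series.m.std()
        poly = np.polynomial.Polynomial(c_hat)
        roots = [r.real for r in poly.deriv().roots() if abs(r.imag) < 1e-8]
        mins = [r for r in roots if poly.deriv().deriv()(r) > 0]
        assert len(mins) == 2
        np.testing.assert_allclose(sorted(np.abs(mins)), [1.0 / sd] * 2, atol=0.1)

    def test_grid_resolution_insensitive(self):
        x = np.random.default_rng(9).standard_normal(20_000)
        x = (x - x.mean()) / x.std()
        cs = []
        for bins in (TEST_BINS, 1_000_000):
            grid, nlp, _ = estimate_neg_log_density(x, n_bins=bins)
            cs.append(fit_energy_polynomial(grid, nlp))
        assert np.max(np.abs(cs[0] - cs[1])) < 1e-3
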