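import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from psqi_geo.mtgpr import PredictiveDistribution
from psqi_geo.preprocess import BoundedWarper
from psqi_geo.psqi import (
    PSQICalculator,
    PSQIWeights,
    apply_fallback,
    fraction_in_bounds,
    marginal_probability,
    softmax_weights,
)
from psqi_geo.standards import effective_bounds


def _pred(mean, cov):
    return PredictiveDistribution(
        location=np.zeros(2), mean=np.asarray(mean, float), covariance=np.asarray(cov, float)
    )


def _mvn_box_mass(mean, cov, i, lo, hi):
    """Integrate the full M-variate Gaussian over the box that constrains only
    coordinate i — an independent oracle for the closed-form marginal."""
    sd = np.sqrt(np.diag(cov))
    lower = mean - 40 * sd
    upper = mean + 40 * sd
    lower[i], upper[i] = lo, hi
    return multivariate_normal.cdf(
        upper, mean=mean, cov=cov, lower_limit=lower, abseps=1e-9, releps=0
    )


class TestMarginalProbability:
    def test_worked_value_95_percent(self):
        p = marginal_probability(_pred([5.0], [[1.0]]), 0, (5 - 1.959964, 5 + 1.959964))
        assert abs(p - 0.95) < 1e-6

    def test_matches_full_multivariate_integration(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            M = rng.integers(2, 5)
            A = rng.normal(size=(M, M))
            cov = A @ A.T + 0.5 * np.eye(M)
            mean = rng.normal(0, 2, M)
            i = int(rng.integers(M))
            lo, hi = sorted(rng.normal(0, 2, 2))
            ours = marginal_probability(_pred(mean, cov), i, (lo, hi))
            oracle = _mvn_box_mass(mean, cov, i, lo, hi)
            assert abs(ours - oracle) < 1e-6

    def test_independent_of_other_components(self):
        mean = np.array([0.5, 10.0, -3.0])
        cov = np.diag([0.2, 9.0, 1.0])
        base = marginal_probability(_pred(mean, cov), 0, (0.0, 1.0))
        cov2 = cov.copy()
        cov2[1, 2] = cov2[2, 1] = 2.5
        mean2 = mean.copy()
        mean2[1:] = [99.0, 99.0]
        assert marginal_probability(_pred(mean2, cov2), 0, (0.0, 1.0)) == base

    def test_degenerate_variance_becomes_indicator(self):
        assert marginal_probability(_pred([0.5, 0], np.zeros((2, 2))), 0, (0, 1)) == 1.0
        assert marginal_probability(_pred([2.0, 0], np.zeros((2, 2))), 0, (0, 1)) == 0.0

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            marginal_probability(_pred([0.0], [[1.0]]), 0, (1.0, 1.0))


class TestWeights:
    def test_softmax_of_one_and_zero(self):
        w = softmax_weights({"a": 1.0, "b": 0.0}).as_dict()
        assert abs(w["a"] - np.e / (np.e + 1)) < 1e-12  # 0.7311…
        assert abs(w["a"] + w["b"] - 1.0) < 1e-15

    def test_negative_scores_behave_as_zero(self):
        w_neg = softmax_weights({"a": 0.5, "b": -3.0}).values
        w_zero = softmax_weights({"a": 0.5, "b": 0.0}).values
        assert np.array_equal(w_neg, w_zero)

    def test_uniform_when_all_equal(self):
        w = softmax_weights({"a": 0.4, "b": 0.4, "c": 0.4}).values
        assert np.max(np.abs(w - 1 / 3)) < 1e-15

    def test_validation(self):
        with pytest.raises(ValueError):
            PSQIWeights(("a", "b"), np.array([0.7, 0.2]))
        with pytest.raises(ValueError):
            softmax_weights({})


class TestFallback:
    mean = np.array([0.3, 0.8, 0.5])
    cov = np.array([[0.04, 0.01, 0.0], [0.01, 0.09, 0.02], [0.0, 0.02, 0.01]])
    ds_mean = np.array([0.4, 0.6, 0.55])
    ds_var = np.array([0.02, 0.05, 0.03])

    def test_identity_when_all_scores_positive(self):
        out = apply_fallback(_pred(self.mean, self.cov), [0.5, 0.4, 0.1],
                             self.ds_mean, self.ds_var)
        assert np.array_equal(out.mean, self.mean)
        assert np.array_equal(out.covariance, self.cov)

    def test_substitution_and_decorrelation(self):
        out = apply_fallback(_pred(self.mean, self.cov), [0.5, -0.2, None],
                             self.ds_mean, self.ds_var)
        assert out.mean[0] == self.mean[0]
        assert out.mean[1] == self.ds_mean[1] and out.mean[2] == self.ds_mean[2]
        assert out.covariance[1, 1] == self.ds_var[1]
        assert out.covariance[0, 1] == 0.0 and out.covariance[1, 2] == 0.0
        assert out.covariance[0, 0] == self.cov[0, 0]
        ev = np.linalg.eigvalsh(out.covariance)
        assert ev.min() > -1e-12

    def test_fallback_is_location_independent(self):
        a = apply_fallback(_pred(self.mean, self.cov), [-1, -1, -1],
                           self.ds_mean, self.ds_var)
        b = apply_fallback(_pred(self.mean + 5, self.cov * 3), [-1, -1, -1],
                           self.ds_mean, self.ds_var)
        assert np.array_equal(a.mean, b.mean)
        assert np.array_equal(a.covariance, b.covariance)


@pytest.fixture(scope="module")
def warped_setup(small_dataset):
    samples, truth = small_dataset
    params = [c for c in samples.columns if c not in ("longitude", "latitude")]
    warper = BoundedWarper(truth.standards).fit(samples[params])
    return truth.standards, warper


class TestCalculator:
    def _calc(self, setup, **kw):
        standards, warper = setup
        return PSQICalculator(standards, warper, **kw)

    def test_index_is_weighted_sum_of_marginals_in_unit_interval(self, warped_setup):
        calc = self._calc(warped_setup)
        rng = np.random.default_rng(1)
        n, k = 200, len(calc.regulated)
        mean = rng.uniform(0, 1, (n, 4))
        covs = np.zeros((n, 4, 4))
        for b in range(n):
            A = rng.normal(0, 0.1, (4, 4))
            covs[b] = A @ A.T
        psqi, conf, p, q = calc.evaluate(mean, covs)
        assert psqi.shape == (n,) and p.shape == (n, k)
        assert np.all((psqi >= 0) & (psqi <= 1)) and np.all((conf >= 0) & (conf <= 1))
        assert np.max(np.abs(psqi - p @ calc.weights.values)) < 1e-14
        assert np.max(np.abs(conf - q @ calc.weights.values)) < 1e-14

    def test_correlations_do_not_change_the_index(self, warped_setup):
        calc = self._calc(warped_setup)
        mean = np.full((1, 4), 0.5)
        var = np.full(4, 0.02)
        diag = np.diag(var)[None]
        corr = diag.copy()
        corr[0, 0, 1] = corr[0, 1, 0] = 0.015
        corr[0, 2, 3] = corr[0, 3, 2] = -0.01
        assert calc.evaluate(mean, diag)[0] == calc.evaluate(mean, corr)[0]

    def test_confidence_equals_index_when_mean_at_midpoints(self, warped_setup):
        calc = self._calc(warped_setup)
        mid = 0.5 * (calc.bounds_warped[:, 0] + calc.bounds_warped[:, 1])
        mean = np.zeros((1, 4))
        mean[0, calc.indices] = mid
        covs = np.diag(np.full(4, 0.01))[None]
        psqi, conf, _, _ = calc.evaluate(mean, covs)
        assert abs(psqi[0] - conf[0]) < 1e-14

    def test_confidence_limits_in_spread(self, warped_setup):
        calc = self._calc(warped_setup)
        mean = np.full((1, 4), 0.5)
        tiny = np.diag(np.full(4, 1e-12))[None]
        huge = np.diag(np.full(4, 1e6))[None]
        assert calc.evaluate(mean, tiny)[1][0] > 1 - 1e-9
        assert calc.evaluate(mean, huge)[1][0] < 1e-2

    def test_index_increases_when_mass_moves_into_bounds(self, warped_setup):
        calc = self._calc(warped_setup)
        lo, hi = calc.bounds_warped[:, 0], calc.bounds_warped[:, 1]
        inside = np.zeros((1, 4))
        inside[0, calc.indices] = 0.5 * (lo + hi)
        outside = np.zeros((1, 4))
        outside[0, calc.indices] = hi + 5 * 0.05
        covs = np.diag(np.full(4, 0.05**2))[None]
        assert calc.evaluate(inside, covs)[0][0] > calc.evaluate(outside, covs)[0][0]

    def test_low_r2_parameter_uses_dataset_marginal(self, warped_setup, small_dataset):
        standards, warper = warped_setup
        samples, truth = small_dataset
        params = [c for c in samples.columns if c not in ("longitude", "latitude")]
        Z = warper.transform(samples[params])
        r2 = {"pH": 0.7, "Hardness": 0.5, "NO3": -0.4}
        calc = PSQICalculator(standards, warper, r2_scores=r2).set_dataset_stats(Z)
        j = calc.regulated.index("NO3")
        mean = np.full((1, 4), 0.5)
        covs = np.diag(np.full(4, 0.01))[None]
        _, _, p, _ = calc.evaluate(mean, covs)
        lo, hi = calc.bounds_warped[j]
        mu, sd = Z[:, calc.indices[j]].mean(), Z[:, calc.indices[j]].std()
        expect = norm.cdf((hi - mu) / sd) - norm.cdf((lo - mu) / sd)
        assert abs(p[0, j] - expect) < 1e-12
        # shifting the model's own prediction cannot move the fallback marginal
        mean2 = mean.copy()
        mean2[0, calc.indices[j]] = 0.99
        assert calc.evaluate(mean2, covs)[2][0, j] == p[0, j]

    def test_fallback_without_dataset_stats_is_an_error(self, warped_setup):
        calc = self._calc(warped_setup, r2_scores={"pH": -1.0})
        with pytest.raises(ValueError, match="dataset statistics"):
            calc.evaluate(np.full((1, 4), 0.5), np.diag(np.full(4, 0.01))[None])

    def test_unregulated_parameter_never_enters(self, warped_setup):
        calc = self._calc(warped_setup)
        assert "Ca" not in calc.regulated
        assert set(calc.regulated) == {"pH", "Hardness", "NO3"}

    def test_naive_mode_is_a_valid_index_but_differs(self, warped_setup):
        standards, warper = warped_setup
        warped = PSQICalculator(standards, warper, space="warped")
        naive = PSQICalculator(standards, warper, space="naive")
        mean = np.full((1, 4), 0.6)
        covs = np.diag(np.full(4, 0.02))[None]
        pw = warped.evaluate(mean, covs)[0][0]
        pn = naive.evaluate(mean, covs)[0][0]
        assert 0 <= pn <= 1
        assert pw != pn  # the warp is nonlinear, so the two modes disagree

    def test_unknown_space_rejected(self, warped_setup):
        with pytest.raises(ValueError, match="space"):
            self._calc(warped_setup, space="exact")


class TestFractionInBounds:
    def test_seventeen_of_eighteen(self, sanpin):
        row = {}
        for spec in sanpin:
            b = effective_bounds(spec)
            # a value just above the lower bound, inside every interval
            row[spec.name] = 0.5 * (b[0] + min(b[1], b[0] + 1.0)) if isinstance(b, tuple) else 1.0
        row["NO3"] = 100.0  # above its admissible limit
        assert fraction_in_bounds(row, sanpin) == pytest.approx(17 / 18)

    def test_unregulated_values_do_not_count(self, sanpin):
        row = {s.name: 0.01 for s in sanpin if s.regulated}
        row["pH"] = 7.0
        base = fraction_in_bounds(row, sanpin)
        row["Ca"] = 1e9
        assert fraction_in_bounds(row, sanpin) == base

    def test_missing_values_are_skipped(self, sanpin):
        assert fraction_in_bounds({"pH": 7.0, "Cl": np.nan}, sanpin) == 1.0
        with pytest.raises(ValueError):
            fraction_in_bounds({"Ca": 50.0}, sanpin)
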