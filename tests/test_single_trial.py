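"""Single-trial likelihoods against independent oracles.

The AR(1)-errors joint density is checked against the dense multivariate
normal with covariance sigma^2 rho^{|i-j|} / (1 - rho^2), built and
evaluated independently through scipy.
"""

import math

import numpy as np
import pytest
from scipy import stats

import nof1bayes as nb
from nof1bayes.single_trial import (
    ar1_exact_loglik,
    ar1_stationary_product_loglik,
    linear_predictor,
)


def mvn_ar1_oracle(y, mean, rho, sigma2):
    """Dense MVN log density with AR(1) covariance (the independent oracle)."""
    n = len(y)
    idx = np.arange(n)
    cov = sigma2 * rho ** np.abs(np.subtract.outer(idx, idx)) / (1.0 - rho**2)
    return stats.multivariate_normal(mean, cov).logpdf(y)


def make_trial(y, treatment=None, time=None):
    y = np.asarray(y, dtype=float)
    n = len(y)
    treatment = np.ones(n, dtype=int) if treatment is None else np.asarray(treatment)
    time = np.arange(n, dtype=float) if time is None else np.asarray(time)
    return nb.TrialDataset(
        "T", time=time, treatment=treatment, value=y,
        period_index=np.zeros(n, dtype=int) if (treatment == 1).all()
        else np.where(treatment == 1, 0, 1),
        K=int(treatment.max()) if treatment.max() > 1 else 2,
        outcome_bounds=(-1e9, 1e9),
    )


class TestMarginalMoments:
    def test_mean_is_direct_substitution(self):
        p = nb.SingleTrialParams(m=50.0, delta=np.array([-3.0]), beta=0.0, sigma2=1.0)
        spec = nb.ModelSpec()
        mean, _ = nb.marginal_moments(p, spec, time=3.0, treatment=2)
        assert mean == pytest.approx(47.0)

    def test_no_autocorrelation_variance(self):
        p = nb.SingleTrialParams(m=0.0, delta=np.array([0.0]), rho_e=0.0, sigma2=4.0)
        _, var = nb.marginal_moments(p, nb.ModelSpec(autocorrelation="ar_errors"), 0.0, 1)
        assert var == pytest.approx(4.0)

    def test_stationary_variance_matches_long_simulation(self, rng):
        # sigma = 2, rho = 0.6: the closed form gives 4 / (1 - 0.36) = 6.25;
        # cross-checked against the empirical variance of a long simulated
        # stationary AR(1) sequence
        p = nb.SingleTrialParams(m=0.0, delta=np.array([0.0]), rho_e=0.6, sigma2=4.0)
        _, var = nb.marginal_moments(p, nb.ModelSpec(autocorrelation="ar_errors"), 0.0, 1)
        assert var == pytest.approx(6.25)
        n = 400_000
        e = np.empty(n)
        e[0] = math.sqrt(6.25) * rng.standard_normal()
        z = 2.0 * rng.standard_normal(n - 1)
        for j in range(1, n):
            e[j] = 0.6 * e[j - 1] + z[j - 1]
        assert np.var(e) == pytest.approx(6.25, rel=0.02)

    def test_variance_monotone_in_abs_rho(self):
        spec = nb.ModelSpec(autocorrelation="ar_errors")
        vars_ = [
            nb.marginal_moments(
                nb.SingleTrialParams(m=0.0, delta=np.array([0.0]), rho_e=r, sigma2=4.0),
                spec, 0.0, 1,
            )[1]
            for r in (0.0, 0.3, -0.5, 0.7, -0.9)
        ]
        order = np.argsort([0.0, 0.3, 0.5, 0.7, 0.9])
        assert all(np.diff(np.array(vars_)[order]) > 0)

    def test_nonstationary_rho_fails(self):
        p = nb.SingleTrialParams(m=0.0, delta=np.array([0.0]), rho_e=1.0, sigma2=1.0)
        with pytest.raises(ValueError, match="rho_e"):
            nb.marginal_moments(p, nb.ModelSpec(autocorrelation="ar_errors"), 0.0, 1)


class TestLoglik:
    def test_rho_zero_equals_independent_normals(self):
        trial = make_trial([1.0, 2.0, 0.5, -1.0])
        p = nb.SingleTrialParams(m=0.3, delta=np.array([0.0]), rho_e=0.0, sigma2=2.0)
        spec = nb.ModelSpec(autocorrelation="ar_errors")
        expect = stats.norm.logpdf(trial.value, 0.3, math.sqrt(2.0)).sum()
        assert nb.loglik(p, spec, trial) == pytest.approx(expect, abs=1e-10)

    def test_rho_zero_modes_coincide(self):
        trial = make_trial([1.0, 2.0, 0.5, -1.0])
        p = nb.SingleTrialParams(m=0.3, delta=np.array([0.0]), rho_e=0.0, sigma2=2.0)
        exact = nb.loglik(p, nb.ModelSpec(autocorrelation="ar_errors"), trial)
        prod = nb.loglik(
            p,
            nb.ModelSpec(autocorrelation="ar_errors", likelihood_mode="stationary_product"),
            trial,
        )
        assert exact == pytest.approx(prod, abs=1e-12)

    def test_fixed_toy_against_mvn_oracle(self):
        y = np.array([49.0, 51.5, 47.0, 50.0])
        trial = make_trial(y)
        p = nb.SingleTrialParams(m=50.0, delta=np.array([0.0]), rho_e=0.5, sigma2=1.0)
        ll = nb.loglik(p, nb.ModelSpec(autocorrelation="ar_errors"), trial)
        mean = np.full(4, 50.0)
        assert ll == pytest.approx(mvn_ar1_oracle(y, mean, 0.5, 1.0), abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_instances_against_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        rho = float(rng.uniform(-0.9, 0.9))
        sigma2 = float(rng.uniform(0.2, 6.0))
        m = float(rng.uniform(-10, 10))
        d = float(rng.uniform(-5, 5))
        treatment = rng.integers(1, 3, n)
        treatment[0] = 1
        y = rng.normal(m, 2.0, n)
        trial = make_trial(y, treatment=np.sort(treatment))
        p = nb.SingleTrialParams(m=m, delta=np.array([d]), rho_e=rho, sigma2=sigma2)
        spec = nb.ModelSpec(autocorrelation="ar_errors")
        mean = linear_predictor(p, spec, trial.time, trial.treatment)
        assert nb.loglik(p, spec, trial) == pytest.approx(
            mvn_ar1_oracle(y, mean, rho, sigma2), abs=1e-8
        )

    def test_gap_handling_equals_marginalized_mvn(self):
        # dropping the middle observation: the exact loglik over the
        # remaining points must equal the dense MVN marginal over them
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 5)
        rho, sigma2 = 0.6, 1.5
        full_idx = np.array([0, 1, 3, 4])
        trial = make_trial(y[full_idx], time=full_idx.astype(float))
        p = nb.SingleTrialParams(m=0.0, delta=np.array([0.0]), rho_e=rho, sigma2=sigma2)
        ll = nb.loglik(p, nb.ModelSpec(autocorrelation="ar_errors"), trial)
        idx = np.arange(5)
        cov = sigma2 * rho ** np.abs(np.subtract.outer(idx, idx)) / (1 - rho**2)
        sub = cov[np.ix_(full_idx, full_idx)]
        expect = stats.multivariate_normal(np.zeros(4), sub).logpdf(y[full_idx])
        assert ll == pytest.approx(expect, abs=1e-10)

    def test_arm_contrast_relabel_invariance(self):
        y = np.array([50.0, 52.0, 47.0, 46.0])
        treatment = np.array([1, 1, 2, 2])
        trial = make_trial(y, treatment=treatment)
        pc = nb.SingleTrialParams(m=51.0, delta=np.array([-4.0]), rho_e=0.4, sigma2=2.0)
        pa = nb.SingleTrialParams(m=np.array([51.0, 47.0]), rho_e=0.4, sigma2=2.0)
        sc = nb.ModelSpec(parameterization="contrast", autocorrelation="ar_errors")
        sa = nb.ModelSpec(parameterization="arm", autocorrelation="ar_errors")
        assert nb.loglik(pc, sc, trial) == pytest.approx(nb.loglik(pa, sa, trial), abs=1e-12)

    def test_all_missing_trial_fails(self):
        trial = nb.TrialDataset(
            "T", time=[0.0, 1.0], treatment=[1, 1], value=[np.nan, np.nan],
            period_index=[0, 0], outcome_bounds=(0, 100),
        )
        p = nb.SingleTrialParams(m=0.0, delta=np.array([0.0]), sigma2=1.0)
        with pytest.raises(ValueError, match="non-missing"):
            nb.loglik(p, nb.ModelSpec(), trial)

    def test_ar_outcomes_conditional_decomposition(self):
        y = np.array([2.0, 1.0, 3.0])
        trial = make_trial(y)
        rho, s2 = 0.5, 1.2
        p = nb.SingleTrialParams(m=1.0, delta=np.array([0.0]), rho_Y=rho, sigma2=s2)
        ll = nb.loglik(p, nb.ModelSpec(autocorrelation="ar_outcomes"), trial)
        expect = stats.norm.logpdf(y[0], 1.0 / (1 - rho), math.sqrt(s2 / (1 - rho**2)))
        for j in (1, 2):
            expect += stats.norm.logpdf(y[j], 1.0 + rho * y[j - 1], math.sqrt(s2))
        assert ll == pytest.approx(expect, abs=1e-10)


class TestGlm:
    def test_bernoulli_even_odds(self):
        y = np.array([1.0, 0.0, 1.0, 1.0, 0.0])
        trial = make_trial(y)
        p = nb.SingleTrialParams(m=0.0, delta=np.array([0.0]))
        spec = nb.ModelSpec(family="bernoulli_logit")
        assert nb.glm_loglik(p, spec, trial) == pytest.approx(5 * math.log(0.5))

    def test_poisson_unit_rate_zero_count(self):
        trial = make_trial([0.0])
        p = nb.SingleTrialParams(m=0.0, delta=np.array([0.0]))
        spec = nb.ModelSpec(family="poisson_log")
        assert nb.glm_loglik(p, spec, trial) == pytest.approx(-1.0)

    def test_identity_link_normal_equals_normal_loglik(self):
        trial = make_trial([1.0, 2.0, 3.0])
        p = nb.SingleTrialParams(m=1.5, delta=np.array([0.0]), sigma2=2.0)
        assert nb.glm_loglik(p, nb.ModelSpec(), trial) == pytest.approx(
            nb.loglik(p, nb.ModelSpec(), trial)
        )

    def test_non_integer_poisson_outcome_fails(self):
        trial = make_trial([1.5])
        p = nb.SingleTrialParams(m=0.0, delta=np.array([0.0]))
        with pytest.raises(ValueError, match="counts"):
            nb.glm_loglik(p, nb.ModelSpec(family="poisson_log"), trial)

    def test_poisson_loglik_concave_in_mean(self):
        # numerical concavity of the log-likelihood in m on a grid
        trial = make_trial([2.0, 1.0, 3.0, 0.0])
        spec = nb.ModelSpec(family="poisson_log")
        grid = np.linspace(-1.0, 1.5, 41)
        ll = np.array([
            nb.glm_loglik(nb.SingleTrialParams(m=g, delta=np.array([0.0])), spec, trial)
            for g in grid
        ])
        second = np.diff(ll, 2)
        assert np.all(second < 1e-9)

    def test_discrete_family_rejects_autocorrelation(self):
        with pytest.raises(ValueError, match="autocorrelation"):
            nb.ModelSpec(family="bernoulli_logit", autocorrelation="ar_errors")


class TestDefaultPriors:
    def test_reporter_scales(self):
        spec = nb.ModelSpec(parameterization="arm")
        parent = nb.default_priors(spec, (38.0, 78.0))
        child = nb.default_priors(spec, (34.0, 78.0))
        assert parent["m"].support == (38.0, 78.0)
        assert child["m"].support == (34.0, 78.0)

    def test_contrast_prior_spans_scale_width(self):
        ps = nb.default_priors(nb.ModelSpec(), (34.0, 78.0))
        assert ps["delta[2]"].support == (-44.0, 44.0)

    def test_rho_and_sigma_priors(self):
        ps = nb.default_priors(nb.ModelSpec(), (34.0, 78.0))
        assert ps["rho_e"].support == (-1.0, 1.0)
        assert ps["sigma"].support == (0.0, 1000.0)
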