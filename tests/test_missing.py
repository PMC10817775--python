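"""MAR conditionals, MNAR stratified imputation, Rubin's-rules pooling."""

import math

import numpy as np
import pytest
from scipy import stats

import nof1bayes as nb
from nof1bayes.mcmc import SamplerConfig, sample
from nof1bayes.missing import ar1_conditional_moments, expand_planned_slots


def trial_with_missing(values, bounds=(-1e9, 1e9)):
    values = np.asarray(values, dtype=float)
    n = len(values)
    return nb.TrialDataset(
        "M", time=np.arange(n, dtype=float), treatment=np.ones(n, dtype=int),
        value=values, period_index=np.zeros(n, dtype=int),
        outcome_bounds=bounds,
    )


class TestMarConditionals:
    def test_interior_point_matches_three_dim_normal_oracle(self):
        # closed-form conditional of a 3-dim normal with AR(1) covariance,
        # computed independently via the partitioned-covariance formula
        rho, sigma2 = 0.5, 1.3
        mean = np.array([1.0, 2.0, 0.5])
        obs = np.array([1.8, np.nan, 0.2])
        svar = sigma2 / (1 - rho**2)
        cov = svar * rho ** np.abs(np.subtract.outer(np.arange(3), np.arange(3)))
        # condition index 1 on (0, 2)
        S12 = cov[1, [0, 2]]
        S22 = cov[np.ix_([0, 2], [0, 2])]
        w = np.linalg.solve(S22, S12)
        expect_mean = mean[1] + w @ (obs[[0, 2]] - mean[[0, 2]])
        expect_var = cov[1, 1] - w @ S12
        got_mean, got_var = ar1_conditional_moments(
            np.arange(3.0), obs, mean, rho, sigma2, 1
        )
        assert got_mean == pytest.approx(expect_mean, abs=1e-8)
        assert got_var == pytest.approx(expect_var, abs=1e-8)

    def test_endpoint_conditions_on_single_neighbor(self):
        rho, sigma2 = 0.6, 2.0
        mean = np.zeros(2)
        obs = np.array([1.0, np.nan])
        got_mean, got_var = ar1_conditional_moments(np.arange(2.0), obs, mean, rho, sigma2, 1)
        svar = sigma2 / (1 - rho**2)
        assert got_mean == pytest.approx(rho * 1.0)
        assert got_var == pytest.approx(svar * (1 - rho**2))

    def test_rho_zero_draw_is_independent(self, rng):
        trial = trial_with_missing([5.0, np.nan, 5.0])
        p = nb.SingleTrialParams(m=2.0, delta=None, rho_e=0.0, sigma2=1.0)
        spec = nb.ModelSpec(parameterization="contrast", autocorrelation="ar_errors")
        draws = np.array([
            nb.impute_mar_draw(trial, p, spec, rng)[1] for _ in range(4000)
        ])
        # neighbors are far from the marginal mean; independence means the
        # draws still center on M_j = 2
        assert draws.mean() == pytest.approx(2.0, abs=0.06)
        assert draws.std() == pytest.approx(1.0, rel=0.06)

    def test_observed_values_never_altered(self, rng):
        trial = trial_with_missing([5.0, np.nan, 3.0, np.nan])
        p = nb.SingleTrialParams(m=4.0, delta=None, rho_e=0.4, sigma2=1.0)
        spec = nb.ModelSpec(parameterization="contrast", autocorrelation="ar_errors")
        out = nb.impute_mar_draw(trial, p, spec, rng)
        assert out[0] == 5.0 and out[2] == 3.0
        assert np.isfinite(out).all()

    def test_truncation_to_bounds(self, rng):
        trial = trial_with_missing([50.0, np.nan, 50.0], bounds=(49.0, 51.0))
        p = nb.SingleTrialParams(m=50.0, delta=None, rho_e=0.0, sigma2=100.0)
        spec = nb.ModelSpec(parameterization="contrast")
        draws = np.array([
            nb.impute_mar_draw(trial, p, spec, rng)[1] for _ in range(100)
        ])
        assert draws.min() >= 49.0 and draws.max() <= 51.0


class TestAugmentationInvariance:
    def test_mar_augmentation_matches_observed_data_posterior(self):
        # 5-observation toy with one interior missing value: data
        # augmentation must leave the parameter posterior unchanged versus
        # analytic marginalization (simply skipping the missing row)
        y = [51.0, np.nan, 49.5, 52.0, 50.5]
        trial = trial_with_missing(y, bounds=(34.0, 78.0))
        spec = nb.ModelSpec(parameterization="contrast", autocorrelation="ar_errors")
        cfg = SamplerConfig(chains=2, warmup=800, draws=3000, seed=21)
        m_aug = nb.assemble_single(trial, spec, impute=True)
        m_marg = nb.assemble_single(trial, spec, impute=False)
        d_aug = sample(m_aug, cfg)
        d_marg = sample(m_marg, cfg)
        for name in ("m", "sigma", "rho_e"):
            a, b = d_aug.stacked(name), d_marg.stacked(name)
            ess = min(nb.effective_sample_size(d_aug)[name],
                      nb.effective_sample_size(d_marg)[name])
            se = math.sqrt(a.var() / ess + b.var() / ess)
            assert abs(a.mean() - b.mean()) < 4 * se, name


class TestExpandSlots:
    def make_rules(self):
        design = nb.DesignTemplate(baseline_weeks=2, n_periods=4, period_weeks=8)
        return nb.ImputationRules(
            min_baseline=1, min_per_period=6, planned_periods=4,
            planned_weeks=design.planned_weeks_by_period("ABAB"),
            period_treatment={
                s: dict(enumerate(design.period_treatments(s), start=1))
                for s in ("ABAB", "BABA")
            },
        )

    def test_absent_periods_get_slots_with_sequence_treatment(self):
        trial = nb.TrialDataset(
            "W", time=[0.0, 2.0, 3.0], treatment=[1, 2, 2],
            value=[50.0, 48.0, 47.0], period_index=[0, 1, 1],
            K=3, outcome_bounds=(34, 78), sequence_label="ABAB",
        )
        out = expand_planned_slots(trial, self.make_rules())
        for p, treat in ((1, 2), (2, 3), (3, 2), (4, 3)):
            sel = out.period_index == p
            assert sel.sum() >= 6, f"period {p}"
            assert (out.treatment[sel] == treat).all()
        assert np.isnan(out.value[out.period_index == 4]).all()
        # observed rows unchanged
        assert out.value[out.time == 2.0][0] == 48.0

    def test_complete_individual_unchanged(self):
        design = nb.DesignTemplate(baseline_weeks=2, n_periods=4, period_weeks=8)
        t, a, p = design.schedule("ABAB")
        trial = nb.TrialDataset(
            "C", time=t, treatment=a, value=np.full(len(t), 50.0),
            period_index=p, K=3, outcome_bounds=(34, 78), sequence_label="ABAB",
        )
        out = expand_planned_slots(trial, self.make_rules())
        assert out.n == trial.n


class TestMnarByGroup:
    def make_two_stratum_data(self):
        # well-separated stratum effect means: completers improve a lot,
        # withdrawals not at all
        design = nb.DesignTemplate(baseline_weeks=2, n_periods=4, period_weeks=4)
        trials = {}
        strata = {}
        rng = np.random.default_rng(14)
        for g, (eff, stratum, n_ind) in enumerate(
            [(-8.0, "full", 4), (0.0, "withdrawal", 4)]
        ):
            for j in range(n_ind):
                ind = f"{stratum[0]}{j}"
                params = nb.SingleTrialParams(
                    m=55.0 + rng.normal(0, 1), delta=np.array([eff, eff]),
                    rho_e=0.0, sigma2=4.0,
                )
                trial = nb.simulate_trial(
                    params, design, rng, sequence="ABAB", K=3,
                    bounds=(0.0, 100.0), individual_id=ind,
                )
                if stratum == "withdrawal":
                    keep = trial.period_index <= 1
                    trial = nb.TrialDataset(
                        ind, trial.time[keep], trial.treatment[keep],
                        trial.value[keep], trial.period_index[keep],
                        K=3, outcome_bounds=(0.0, 100.0), sequence_label="ABAB",
                    )
                trials[ind] = trial
                strata[ind] = stratum
        return nb.MultiTrialDataset(trials=trials, completion_stratum=strata), design

    def test_m_imputations_and_observed_cells_identical(self):
        data, design = self.make_two_stratum_data()
        rules = nb.ImputationRules(
            min_baseline=1, min_per_period=3, planned_periods=4,
            planned_weeks=design.planned_weeks_by_period("ABAB"),
            period_treatment={"ABAB": dict(enumerate(design.period_treatments("ABAB"), start=1))},
        )
        cfg = SamplerConfig(chains=2, warmup=150, draws=150, seed=5)
        res = nb.impute_mnar_by_group(data, M=5, rules=rules, sampler=cfg, seed=5)
        assert res.M == 5 and len(res.completed_datasets) == 5
        ind = "f0"
        obs = data.trials[ind].observed
        for ds in res.completed_datasets:
            t2 = ds.trials[ind]
            t2.validate()
            np.testing.assert_array_equal(
                t2.value[: len(obs)][obs], data.trials[ind].value[obs]
            )
            assert np.isfinite(t2.value).all()

    def test_withdrawal_imputations_use_own_stratum_posterior(self):
        data, design = self.make_two_stratum_data()
        rules = nb.ImputationRules(
            min_baseline=1, min_per_period=3, planned_periods=4,
            planned_weeks=design.planned_weeks_by_period("ABAB"),
            period_treatment={"ABAB": dict(enumerate(design.period_treatments("ABAB"), start=1))},
        )
        cfg = SamplerConfig(chains=2, warmup=200, draws=200, seed=6)
        res = nb.impute_mnar_by_group(data, M=8, rules=rules, sampler=cfg, seed=6)
        # withdrawals never saw periods 3-4; their imputed diet outcomes
        # must reflect the withdrawal stratum (no benefit: level ~ 55),
        # not the completer stratum (benefit: level ~ 47)
        imputed = []
        for ds in res.completed_datasets:
            for ind in data.ids:
                if data.completion_stratum[ind] != "withdrawal":
                    continue
                t2 = ds.trials[ind]
                orig = data.trials[ind]
                new = ~np.isin(t2.time, orig.time)
                sel = new & (t2.period_index >= 3)
                imputed.extend(t2.value[sel].tolist())
        imputed = np.array(imputed)
        assert len(imputed) > 20
        assert abs(imputed.mean() - 55.0) < 3.0
        assert imputed.mean() > 51.0  # clearly not the completer level


class TestRubinPool:
    def test_single_imputation(self):
        est, tot, (lo, hi) = nb.rubin_pool([2.5], [0.81])
        assert est == 2.5 and tot == 0.81
        assert lo == pytest.approx(2.5 - 1.959964 * 0.9, abs=1e-4)

    def test_identical_estimates_no_between_variance(self):
        est, tot, _ = nb.rubin_pool([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])
        assert est == 3.0 and tot == pytest.approx(2.0)

    def test_printed_example(self):
        est, tot, _ = nb.rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert est == pytest.approx(2.0)
        assert tot == pytest.approx(1.0 + (1 + 1 / 3) * 1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_sets_against_independent_formulas(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(2, 9))
        q = rng.normal(0, 3, M)
        u = rng.uniform(0.1, 2, M)
        est, tot, (lo, hi) = nb.rubin_pool(q, u, 0.95)
        W = u.mean()
        B = q.var(ddof=1)
        T = W + (1 + 1 / M) * B
        assert est == pytest.approx(q.mean(), abs=1e-12)
        assert tot == pytest.approx(T, abs=1e-12)
        nu = (M - 1) * (1 + W / ((1 + 1 / M) * B)) ** 2
        crit = stats.t.ppf(0.975, df=nu)
        assert hi - lo == pytest.approx(2 * crit * math.sqrt(T), abs=1e-10)
        assert tot >= W  # total variance never below within-imputation mean

    def test_empty_fails(self):
        with pytest.raises(ValueError):
            nb.rubin_pool([], [])
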