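"""Missing-outcome handling: MAR data augmentation and MNAR multiple imputation.

Under missingness at random, a missing outcome is just another unknown in
the Bayesian model: inside the sampler it is drawn from its exact
conditional normal given the observed neighbors and the current parameter
values (:func:`impute_mar_draw`), which is data augmentation.

When missingness depends on unobserved benefit -- participants who drop
out early tend to be the ones a diet was not helping -- MAR imputation
from the pooled model is biased.  The procedure here stratifies on the
three completion groups (full completers, early completers, withdrawals),
fits the multilevel model within each stratum alone, imputes each
individual's missing design slots from their own stratum's posterior, and
returns M completed datasets whose analyses are pooled with Rubin's rules
(:func:`rubin_pool`).
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .mcmc import SamplerConfig, sample
from .multilevel import LevelSpec, assemble_multilevel
from .single_trial import ModelSpec, SingleTrialParams, linear_predictor
from .trial_data import MultiTrialDataset, TrialDataset

logger = logging.getLogger("nof1bayes")


# ---------------------------------------------------------------------------
# exact AR(1) conditionals
# ---------------------------------------------------------------------------

def ar1_conditional_moments(
    times: np.ndarray,
    filled: np.ndarray,
    mean: np.ndarray,
    rho: float,
    sigma2: float,
    j: int,
) -> tuple[float, float]:
    """Conditional mean and variance of slot ``j`` given its nearest
    filled neighbors under stationary AR(1) errors.

    The error process has covariance sigma^2 rho^{|t_a - t_b|} / (1 - rho^2)
    between slots at times t_a, t_b.  Conditioning an AR(1) on all other
    slots reduces to conditioning on the nearest filled neighbor on each
    side (the process is Markov), so the moments come from the 2- or 3-
    dimensional normal of (Y_j, neighbors).
    """
    svar = sigma2 / (1.0 - rho**2)
    nbrs = []
    for idx in range(j - 1, -1, -1):
        if np.isfinite(filled[idx]):
            nbrs.append(idx)
            break
    for idx in range(j + 1, len(filled)):
        if np.isfinite(filled[idx]):
            nbrs.append(idx)
            break
    if not nbrs:
        return float(mean[j]), float(svar)
    pts = [j] + nbrs
    tt = times[pts]
    lag = np.abs(tt[:, None] - tt[None, :])
    if rho == 0.0:
        corr = (lag == 0).astype(float)
    elif np.all(np.abs(lag - np.round(lag)) < 1e-9):
        corr = np.float_power(rho, np.round(lag))
    else:
        if rho < 0:
            raise ValueError("non-integer gaps need rho >= 0")
        corr = np.power(rho, lag)
    S = svar * corr
    dev = filled[nbrs] - mean[nbrs]
    S12 = S[0, 1:]
    S22 = S[1:, 1:]
    w = np.linalg.solve(S22, S12)
    cmean = float(mean[j] + w @ dev)
    cvar = float(S[0, 0] - w @ S12)
    return cmean, max(cvar, 1e-12)


def impute_mar_draw(
    trial: TrialDataset,
    params: SingleTrialParams,
    spec: ModelSpec,
    rng: np.random.Generator,
    filled: np.ndarray | None = None,
    truncate: bool = True,
) -> np.ndarray:
    """Draw values for the missing slots of a trial from their conditionals.

    Missing slots are visited in order; each is drawn from its exact
    conditional normal given the currently filled values of its neighbors
    (one Gibbs scan of the augmented outcomes).  Without autocorrelation
    the draw is independent, N(M_j, sigma^2).  Observed values are never
    altered.  Draws are truncated to the declared outcome bounds when
    ``truncate`` (truncation logged).
    """
    out = trial.value.copy() if filled is None else filled.copy()
    missing = np.flatnonzero(~trial.observed)
    if missing.size == 0:
        return out
    mean = linear_predictor(params, spec, trial.time, trial.treatment)
    lo, hi = trial.outcome_bounds
    use_ar = spec.autocorrelation == "ar_errors" and params.rho_e != 0.0
    for j in missing:
        if use_ar:
            hold = out[j]
            out[j] = np.nan
            cmean, cvar = ar1_conditional_moments(
                trial.time, out, mean, params.rho_e, params.sigma2, j
            )
            out[j] = hold
        else:
            cmean, cvar = float(mean[j]), params.sigma2
        draw = cmean + math.sqrt(cvar) * rng.standard_normal()
        if truncate and not (lo <= draw <= hi):
            logger.info(
                "imputed value %.2f for %s at week %g truncated to [%g, %g]",
                draw, trial.individual_id, trial.time[j], lo, hi,
            )
            draw = min(max(draw, lo), hi)
        out[j] = draw
    return out


# ---------------------------------------------------------------------------
# MNAR group-stratified multiple imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationRules:
    """Minimum-measurement rules and planned schedule for imputation.

    After imputation every individual has at least ``min_baseline``
    baseline measurements and at least ``min_per_period`` in each of the
    ``planned_periods`` experimental periods.  ``planned_weeks`` maps a
    period index to the week times at which measurements were scheduled
    (used to create design slots for periods the participant never
    entered); ``period_treatment`` maps a period index to its treatment
    code given the individual's randomization sequence.
    """

    min_baseline: int = 1
    min_per_period: int = 6
    planned_periods: int = 4
    planned_weeks: dict[int, list[float]] = field(default_factory=dict)
    period_treatment: dict[str, dict[int, int]] = field(default_factory=dict)


@dataclass
class ImputationResult:
    completed_datasets: list[MultiTrialDataset]
    M: int
    summaries: list = field(default_factory=list)
    pooled: dict | None = None


def expand_planned_slots(trial: TrialDataset, rules: ImputationRules) -> TrialDataset:
    """Add NaN design slots until the minimum-measurement rules are met.

    For each period short of its minimum, the earliest planned weeks not
    already present are appended as missing rows (treatment taken from the
    period's rows if present, else from the sequence mapping in rules).
    """
    times = list(trial.time)
    treatments = list(trial.treatment)
    values = list(trial.value)
    periods = list(trial.period_index)
    seq_map = rules.period_treatment.get(trial.sequence_label, {})

    def count(p: int) -> int:
        return sum(1 for q in periods if q == p)

    for p in range(0, rules.planned_periods + 1):
        need = rules.min_baseline if p == 0 else rules.min_per_period
        planned = rules.planned_weeks.get(p, [])
        have = count(p)
        if have >= need:
            continue
        present_weeks = {t for t, q in zip(times, periods) if q == p}
        if p == 0 or any(q == p for q in periods):
            rows = [k for k, q in enumerate(periods) if q == p]
            treat = treatments[rows[0]] if rows else 1
        else:
            treat = seq_map.get(p)
            if treat is None:
                # alternating (ABAB/BABA) design: any observed period of
                # the same parity pins down the treatment
                parity = {q % 2: treatments[k] for k, q in enumerate(periods) if q >= 1}
                treat = parity.get(p % 2)
            if treat is None:
                raise ValueError(
                    f"{trial.individual_id}: no treatment mapping for period {p} "
                    f"(sequence {trial.sequence_label!r})"
                )
        for w in planned:
            if have >= need:
                break
            if w in present_weeks:
                continue
            times.append(w)
            treatments.append(treat)
            values.append(np.nan)
            periods.append(p)
            have += 1
        if have < need:
            logger.warning(
                "%s: period %d still below minimum (%d < %d) after expansion",
                trial.individual_id, p, have, need,
            )
    order = np.argsort(times, kind="stable")
    return replace(
        trial,
        time=np.asarray(times, float)[order],
        treatment=np.asarray(treatments, int)[order],
        value=np.asarray(values, float)[order],
        period_index=np.asarray(periods, int)[order],
    )


def _stratum_draw_params(draws, idx: int, ind: str, K: int, rng: np.random.Generator):
    """First-level parameters for one individual from one posterior draw.

    Individuals fitted in the stratum model have their own mu[i] and
    delta[i,k]; a contrast never informed by data still has a posterior
    (its hierarchical prior mixture), so every slot is available.
    """
    flat = {n: draws.stacked(n) for n in draws.names()}

    def get(name, fallback=None):
        if name in flat:
            return float(flat[name][idx])
        return fallback

    mu = get(f"mu[{ind}]", get("mu"))
    deltas = []
    for k in range(2, K + 1):
        dk = get(f"delta[{ind},{k}]", get(f"d[{k}]", get(f"d0[{k}]")))
        if dk is None:
            raise ValueError(f"no effect draw for treatment {k}")
        deltas.append(dk)
    rho = get(f"rho_e[{ind}]", get("rho_e", 0.0))
    sigma = get(f"sigma[{ind}]", get("sigma"))
    return SingleTrialParams(
        m=mu, delta=np.array(deltas), rho_e=rho, sigma2=sigma**2
    )


def impute_mnar_by_group(
    data: MultiTrialDataset,
    M: int = 5,
    rules: ImputationRules | None = None,
    spec: ModelSpec | None = None,
    level: LevelSpec | None = None,
    sampler: SamplerConfig | None = None,
    seed: int = 0,
) -> ImputationResult:
    """Completion-stratum-specific multiple imputation.

    Fits the multilevel model separately within each completion stratum,
    then builds ``M`` completed datasets: each individual's missing design
    slots (expanded per ``rules``) are drawn from their own stratum's
    posterior, never from another stratum's.  Observed cells are identical
    across the M datasets.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if rules is None:
        rules = ImputationRules()
    if spec is None:
        spec = ModelSpec(parameterization="contrast", autocorrelation="ar_errors")
    if level is None:
        level = LevelSpec(intercepts="fixed", effects="random",
                          correlations="common", residual="common")
    if sampler is None:
        sampler = SamplerConfig(chains=2, warmup=400, draws=400, seed=seed)

    strata: dict[str, list[str]] = {}
    for ind in data.ids:
        s = data.completion_stratum.get(ind)
        if s is None:
            raise ValueError(f"{ind}: completion stratum not assigned")
        strata.setdefault(s, []).append(ind)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**20]))
    completed_values: dict[str, list[TrialDataset]] = {}
    for sname, members in sorted(strata.items()):
        subset = data.subset(members)
        usable = [i for i in members if subset.trials[i].n_observed > 0]
        if not usable:
            raise ValueError(f"stratum {sname!r} has no usable data")
        fit_subset = subset.subset(usable)
        model = assemble_multilevel(fit_subset, spec, level)
        cfg = replace(sampler, seed=int(np.random.SeedSequence(
            [sampler.seed, zlib.crc32(sname.encode())]).generate_state(1)[0] % (2**31)))
        draws = sample(model, cfg)
        K = next(iter(subset.trials.values())).K
        n_total = draws.n_chains * draws.n_draws
        take = np.linspace(0, n_total - 1, M).astype(int)
        for ind in members:
            trial = expand_planned_slots(subset.trials[ind], rules)
            per_m = []
            for m_i in range(M):
                params = _stratum_draw_params(draws, int(take[m_i]), ind, K, rng)
                filled = impute_mar_draw(trial, params, spec, rng)
                per_m.append(replace(trial, value=filled))
            completed_values[ind] = per_m

    datasets = []
    for m_i in range(M):
        trials = {ind: completed_values[ind][m_i] for ind in data.ids}
        datasets.append(
            MultiTrialDataset(
                trials=trials,
                individual_covariates=data.individual_covariates,
                within_covariates=data.within_covariates,
                completion_stratum=dict(data.completion_stratum),
                washout_applied=data.washout_applied,
            )
        )
    return ImputationResult(completed_datasets=datasets, M=M)


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

def rubin_pool(
    estimates, variances, level: float = 0.95
) -> tuple[float, float, tuple[float, float]]:
    """Pool M completed-data analyses with Rubin's rules.

    pooled estimate  Q = mean(Q_m)
    within variance  W = mean(U_m)
    between variance B = var(Q_m, ddof=1)
    total variance   T = W + (1 + 1/M) B

    The interval is Q +/- t_nu sqrt(T) with the small-M degrees of freedom
    nu = (M - 1) (1 + W / ((1 + 1/M) B))^2; with no between-imputation
    variance (B = 0, including M = 1) the normal reference is used.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.size == 0:
        raise ValueError("need at least one imputation")
    if q.shape != u.shape:
        raise ValueError("estimates and variances must have equal length")
    if np.any(u < 0):
        raise ValueError("variances must be >= 0")
    M = q.size
    qbar = float(q.mean())
    W = float(u.mean())
    B = float(q.var(ddof=1)) if M > 1 else 0.0
    T = W + (1.0 + 1.0 / M) * B
    alpha = 1.0 - level
    if B > 0.0 and M > 1:
        nu = (M - 1) * (1.0 + W / ((1.0 + 1.0 / M) * B)) ** 2
        crit = float(stats.t.ppf(1.0 - alpha / 2.0, df=nu))
    else:
        crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    half = crit * math.sqrt(T)
    return qbar, T, (qbar - half, qbar + half)
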