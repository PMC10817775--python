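"""Predictive distributions, posterior predictive checks and decision summaries.

Decision summaries follow the reporting used for bounded pain outcomes:
for each treatment comparison the posterior median difference, a central
credible interval, the probability of clinically meaningful improvement
(a difference beyond the minimal clinically important difference, MCID,
in the beneficial direction) and of any worsening, and a responder flag
(probability of meaningful improvement above a threshold AND probability
of worsening below a threshold).  By default lower outcome values are
better (pain interference), so improvement means difference < 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .mcmc import PosteriorDraws
from .single_trial import ModelSpec, SingleTrialParams, linear_predictor


@dataclass(frozen=True)
class DecisionSummary:
    comparison: str
    median: float
    lower: float
    upper: float
    p_improve: float
    p_worsen: float
    responder: bool

    def as_row(self) -> dict:
        return {
            "comparison": self.comparison,
            "median": self.median,
            "lower": self.lower,
            "upper": self.upper,
            "p_improve": self.p_improve,
            "p_worsen": self.p_worsen,
            "responder": self.responder,
        }


# ---------------------------------------------------------------------------
# forward simulation and posterior predictive
# ---------------------------------------------------------------------------

def simulate_outcomes(
    params: SingleTrialParams,
    spec: ModelSpec,
    times: np.ndarray,
    treatments: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One forward draw of an outcome series under the model at a design."""
    times = np.asarray(times, dtype=float)
    treatments = np.asarray(treatments, dtype=int)
    mean = linear_predictor(params, spec, times, treatments)
    n = len(times)
    if spec.family == "bernoulli_logit":
        p = 1.0 / (1.0 + np.exp(-mean))
        return (rng.random(n) < p).astype(float)
    if spec.family == "poisson_log":
        return rng.poisson(np.exp(mean)).astype(float)
    sd = math.sqrt(params.sigma2)
    if spec.autocorrelation == "ar_errors" and params.rho_e != 0.0:
        rho = params.rho_e
        svar = params.sigma2 / (1.0 - rho**2)
        e = np.empty(n)
        e[0] = math.sqrt(svar) * rng.standard_normal()
        dt = np.diff(times)
        for j in range(1, n):
            r = rho ** dt[j - 1]
            e[j] = r * e[j - 1] + math.sqrt(svar * (1.0 - r**2)) * rng.standard_normal()
        return mean + e
    if spec.autocorrelation == "ar_outcomes" and params.rho_Y != 0.0:
        rho = params.rho_Y
        y = np.empty(n)
        y[0] = mean[0] / (1.0 - rho) + math.sqrt(params.sigma2 / (1.0 - rho**2)) * rng.standard_normal()
        for j in range(1, n):
            y[j] = mean[j] + rho * y[j - 1] + sd * rng.standard_normal()
        return y
    return mean + sd * rng.standard_normal(n)


def _params_at(draws: PosteriorDraws, idx: int, spec: ModelSpec, K: int) -> SingleTrialParams:
    flat = {n: draws.stacked(n) for n in draws.names()}

    def get(name, default=0.0):
        return float(flat[name][idx]) if name in flat else default

    if spec.parameterization == "arm":
        m = np.array([get(f"m[{k}]") for k in range(1, K + 1)])
        delta = None
    else:
        m = get("m")
        delta = np.array([get(f"delta[{k}]") for k in range(2, K + 1)])
    return SingleTrialParams(
        m=m,
        delta=delta,
        beta=get("beta"),
        rho_e=get("rho_e"),
        rho_Y=get("rho_Y"),
        sigma2=get("sigma", 1.0) ** 2,
    )


def posterior_predictive(
    draws: PosteriorDraws,
    spec: ModelSpec,
    times: np.ndarray,
    treatments: np.ndarray,
    K: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draws of new outcomes at a new design, one row per posterior draw.

    Integrates parameter uncertainty (the posterior draw) with sampling
    variability (a fresh forward simulation per draw), so predictive
    intervals are wider than parameter credible intervals.
    """
    treatments = np.asarray(treatments, dtype=int)
    if treatments.size and (treatments.min() < 1 or treatments.max() > K):
        raise ValueError(f"design references treatment outside 1..{K}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = draws.n_chains * draws.n_draws
    out = np.empty((n, len(times)))
    for i in range(n):
        params = _params_at(draws, i, spec, K)
        out[i] = simulate_outcomes(params, spec, times, treatments, rng)
    return out


def ppc_pvalue(
    draws: PosteriorDraws,
    trial,
    statistic: Callable[[np.ndarray, SingleTrialParams], float],
    spec: ModelSpec,
    seed: int | np.random.Generator = 0,
    max_draws: int | None = None,
) -> float:
    """Posterior predictive p value for a test statistic T(y, theta).

    For each posterior draw l, data y_rep are replicated at the observed
    design and the proportion of draws with
    T(y_rep, theta_l) >= T(y_obs, theta_l) is returned (ties count as
    exceedance, exactly the printed inequality).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = trial.observed
    t, a, y = trial.time[obs], trial.treatment[obs], trial.value[obs]
    n = draws.n_chains * draws.n_draws
    idx = np.arange(n)
    if max_draws is not None and n > max_draws:
        idx = np.linspace(0, n - 1, max_draws).astype(int)
    hits = 0
    for i in idx:
        params = _params_at(draws, int(i), spec, trial.K)
        yrep = simulate_outcomes(params, spec, t, a, rng)
        t_rep = statistic(yrep, params)
        t_obs = statistic(y, params)
        if not (np.isfinite(t_rep) and np.isfinite(t_obs)):
            raise ValueError("test statistic is not finite")
        if t_rep >= t_obs:
            hits += 1
    return hits / len(idx)


# ---------------------------------------------------------------------------
# decision summaries
# ---------------------------------------------------------------------------

def classify_responder(
    effect_draws: np.ndarray,
    comparison: str = "effect",
    mcid: float = 3.0,
    p_improve: float = 0.5,
    p_worse: float = 0.1,
    lower_is_better: bool = True,
    level: float = 0.95,
) -> DecisionSummary:
    """Classify a treatment comparison from draws of the outcome difference.

    Improvement is a difference beyond ``mcid`` in the beneficial
    direction (difference < -mcid when lower outcomes are better);
    worsening is any difference in the harmful direction.  The responder
    flag requires P(meaningful improvement) > ``p_improve`` and
    P(worsening) < ``p_worse``.
    """
    x = np.asarray(effect_draws, dtype=float)
    if x.size == 0:
        raise ValueError("no effect draws supplied")
    if mcid <= 0:
        raise ValueError("mcid must be > 0")
    if not lower_is_better:
        x = -x
    pi = float(np.mean(x < -mcid))
    pw = float(np.mean(x > 0.0))
    alpha = (1.0 - level) / 2.0
    lo, med, hi = np.percentile(effect_draws, [100 * alpha, 50.0, 100 * (1 - alpha)])
    return DecisionSummary(
        comparison=comparison,
        median=float(med),
        lower=float(lo),
        upper=float(hi),
        p_improve=pi,
        p_worsen=pw,
        responder=bool(pi > p_improve and pw < p_worse),
    )


def comparison_draws(
    draws: PosteriorDraws, a, b=None, parameterization: str = "arm"
) -> np.ndarray:
    """Per-draw difference for a treatment comparison.

    Arm form: difference of arm means ``m[a] - m[b]``.  Contrast form:
    ``delta[a]`` against the reference (b None or 1), else
    ``delta[a] - delta[b]``.
    """
    if parameterization == "arm":
        return draws.stacked(f"m[{a}]") - draws.stacked(f"m[{b}]")
    n = draws.n_chains * draws.n_draws

    def contrast(k):
        return draws.stacked(f"delta[{k}]") if k not in (None, 1) else np.zeros(n)

    return contrast(a) - contrast(b)


def benefit_harm_table(
    draws: PosteriorDraws,
    comparisons: list[tuple[str, int, int]],
    parameterization: str = "arm",
    mcid: float = 3.0,
    p_improve: float = 0.5,
    p_worse: float = 0.1,
    lower_is_better: bool = True,
    level: float = 0.95,
) -> pd.DataFrame:
    """One decision-summary row per treatment comparison.

    ``comparisons`` is a list of (label, a, b) treatment-code pairs, e.g.
    ("SCD v Baseline", 2, 1).  Columns: median, the credible-interval
    endpoints, P(difference < 0) (the benefit probability when lower is
    better), P(meaningful improvement), P(worsening), responder flag.
    """
    rows = []
    for label, a, b in comparisons:
        try:
            diff = comparison_draws(draws, a, b, parameterization)
        except KeyError as exc:
            raise ValueError(f"comparison {label!r}: unknown parameter {exc}") from None
        ds = classify_responder(
            diff, label, mcid=mcid, p_improve=p_improve, p_worse=p_worse,
            lower_is_better=lower_is_better, level=level,
        )
        row = ds.as_row()
        row["p_below_zero"] = float(np.mean(diff < 0.0))
        rows.append(row)
    return pd.DataFrame(rows).set_index("comparison")
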