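"""Synthetic multi-individual N-of-1 datasets with known ground truth.

The generator emulates a diet-crossover study design in children with
inflammatory bowel disease: a 2-week baseline period on the usual diet
(treatment 1), followed by four 8-week experimental periods alternating
two diets in an ABAB or BABA sequence, with weekly measurements of a
bounded continuous outcome (a PROMIS-style T-score).  Outcomes follow the
contrast-based first-level model with stationary AR(1) errors; individual
parameters are drawn from the second-level random-effects distributions.

Participants fall into three completion strata: full completers (all four
periods), early completers (stopped after a single crossover, periods 1-2)
and withdrawals (dropped out during period 1 or 2).  Default stratum
proportions are 21/54, 9/54 and 24/54.  Dropout can be made informative
(missing-not-at-random): the probability of withdrawing is tilted by the
individual's realized treatment benefit, so participants a diet was not
helping leave earlier.  Intermittent missing-at-random gaps are added on
top at a configurable rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .multilevel import HyperParams, build_sigma_mu_delta
from .single_trial import ModelSpec, SingleTrialParams
from .trial_data import (
    COMPLETION_EARLY,
    COMPLETION_FULL,
    COMPLETION_WITHDRAWAL,
    MultiTrialDataset,
    TrialDataset,
)


@dataclass(frozen=True)
class DesignTemplate:
    """Measurement schedule of the crossover design.

    Weekly measurements; baseline weeks 0..baseline_weeks-1 on the
    reference treatment, then ``n_periods`` experimental periods of
    ``period_weeks`` weeks each.  ``sequences`` maps a sequence label to
    the treatment codes of the experimental periods in order.
    """

    baseline_weeks: int = 2
    n_periods: int = 4
    period_weeks: int = 8
    sequences: tuple[str, ...] = ("ABAB", "BABA")

    def period_treatments(self, sequence: str, K: int = 3) -> list[int]:
        codes = {"A": 2, "B": min(3, K)}
        return [codes[c] for c in sequence[: self.n_periods]]

    def schedule(self, sequence: str, K: int = 3):
        """(times, treatments, period_index) for the full planned grid."""
        times, treatments, periods = [], [], []
        w = 0
        for _ in range(self.baseline_weeks):
            times.append(float(w)); treatments.append(1); periods.append(0)
            w += 1
        for p, treat in enumerate(self.period_treatments(sequence, K), start=1):
            for _ in range(self.period_weeks):
                times.append(float(w)); treatments.append(treat); periods.append(p)
                w += 1
        return (
            np.array(times), np.array(treatments, dtype=int), np.array(periods, dtype=int)
        )

    def planned_weeks_by_period(self, sequence: str, K: int = 3) -> dict[int, list[float]]:
        t, _, p = self.schedule(sequence, K)
        return {int(q): [float(x) for x in t[p == q]] for q in np.unique(p)}


@dataclass
class DropoutModel:
    """Completion-stratum assignment and dropout timing.

    ``stratum_probs`` are the baseline probabilities of (full, early,
    withdrawal).  ``mnar_strength`` > 0 makes withdrawal more likely for
    individuals with less realized benefit: the withdrawal weight is
    multiplied by exp(mnar_strength * delta_i2) (a negative contrast =
    benefit = smaller weight).  ``mar_rate`` is the probability that any
    scheduled measurement is intermittently missing.
    """

    stratum_probs: tuple[float, float, float] = (21 / 54, 9 / 54, 24 / 54)
    mnar_strength: float = 0.0
    mar_rate: float = 0.05


@dataclass
class SimulationTruth:
    """Everything needed to score recovery against the generated data."""

    hyper: HyperParams
    design: DesignTemplate
    dropout: DropoutModel
    individual_params: dict[str, dict] = field(default_factory=dict)
    strata: dict[str, str] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)
    n_truncated: int = 0

    def to_json(self, path) -> None:
        payload = {
            "hyper": asdict(self.hyper),
            "design": asdict(self.design),
            "dropout": asdict(self.dropout),
            "individual_params": self.individual_params,
            "strata": self.strata,
            "sequences": self.sequences,
            "n_truncated": self.n_truncated,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=list)


def simulate_trial(
    params: SingleTrialParams,
    design: DesignTemplate,
    seed: int | np.random.Generator = 0,
    sequence: str = "ABAB",
    K: int = 3,
    bounds: tuple[float, float] = (34.0, 78.0),
    individual_id: str = "1",
    truncation_log: list | None = None,
) -> TrialDataset:
    """Generate one trial's weekly outcomes with stationary AR(1) errors.

    Values falling outside the outcome bounds are clipped (the scale is
    bounded by construction) and the event recorded in ``truncation_log``.
    Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times, treatments, periods = design.schedule(sequence, K)
    n = len(times)
    delta = params.delta if params.delta is not None else np.zeros(K - 1)
    mean = np.full(n, float(params.m))
    nonref = treatments > 1
    mean[nonref] += np.asarray(delta)[treatments[nonref] - 2]
    mean += params.beta * times

    rho = params.rho_e
    sd = math.sqrt(params.sigma2)
    if params.sigma2 == 0.0:
        y = mean.copy()
    elif rho != 0.0:
        svar = params.sigma2 / (1.0 - rho**2)
        e = np.empty(n)
        e[0] = math.sqrt(svar) * rng.standard_normal()
        z = rng.standard_normal(n - 1)
        for j in range(1, n):
            e[j] = rho * e[j - 1] + sd * z[j - 1]
        y = mean + e
    else:
        y = mean + sd * rng.standard_normal(n)

    lo, hi = bounds
    clipped = (y < lo) | (y > hi)
    if clipped.any():
        if truncation_log is not None:
            truncation_log.append((individual_id, int(clipped.sum())))
        y = np.clip(y, lo, hi)
    return TrialDataset(
        individual_id=individual_id,
        time=times,
        treatment=treatments,
        value=y,
        period_index=periods,
        K=K,
        outcome_bounds=bounds,
        sequence_label=sequence,
    )


def draw_individual_params(
    hyper: HyperParams, rng: np.random.Generator, mu_delta_correlated: bool = False
) -> SingleTrialParams:
    """One draw of first-level parameters from the second-level model."""
    K = hyper.K
    if mu_delta_correlated and (hyper.sigma_mu > 0 and hyper.sigma_delta > 0):
        S = build_sigma_mu_delta(hyper.sigma_mu, hyper.sigma_delta, hyper.rho_mu_delta, K)
        v = np.concatenate([[hyper.m], hyper.d]) + np.linalg.cholesky(S) @ rng.standard_normal(K)
        mu, delta = float(v[0]), v[1:]
    else:
        mu = hyper.m + hyper.sigma_mu * rng.standard_normal()
        delta = np.asarray(hyper.d) + hyper.sigma_delta * rng.standard_normal(K - 1)
    beta = hyper.b + hyper.sigma_beta * rng.standard_normal()
    ze = hyper.ze + hyper.sigma_ze * rng.standard_normal()
    return SingleTrialParams(
        m=mu, delta=delta, beta=beta, rho_e=math.tanh(ze), sigma2=hyper.sigma**2
    )


def simulate_population(
    hyper: HyperParams,
    n: int,
    design: DesignTemplate | None = None,
    dropout: DropoutModel | None = None,
    seed: int = 0,
    bounds: tuple[float, float] = (34.0, 78.0),
    mu_delta_correlated: bool = False,
) -> tuple[MultiTrialDataset, SimulationTruth]:
    """Generate a population of trials plus its ground truth.

    Per individual: draw first-level parameters from the hierarchy,
    generate the full planned series, assign a completion stratum (with
    the MNAR tilt if configured), truncate the series accordingly, and
    blank intermittent measurements at the MAR rate (rows kept with NaN).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    design = design or DesignTemplate()
    dropout = dropout or DropoutModel()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    truth = SimulationTruth(hyper=hyper, design=design, dropout=dropout)
    trials: dict[str, TrialDataset] = {}
    trunc: list = []
    K = hyper.K

    base = np.asarray(dropout.stratum_probs, dtype=float)
    for i in range(1, n + 1):
        ind = f"P{i:03d}"
        params = draw_individual_params(hyper, rng, mu_delta_correlated)
        seq = design.sequences[(i - 1) % len(design.sequences)]
        trial = simulate_trial(
            params, design, rng, sequence=seq, K=K, bounds=bounds,
            individual_id=ind, truncation_log=trunc,
        )

        w = base.copy()
        if dropout.mnar_strength != 0.0 and params.delta is not None:
            w[2] *= math.exp(dropout.mnar_strength * float(params.delta[0]))
            w /= w.sum()
        stratum = (COMPLETION_FULL, COMPLETION_EARLY, COMPLETION_WITHDRAWAL)[
            rng.choice(3, p=w / w.sum())
        ]

        keep = np.ones(trial.n, dtype=bool)
        if stratum == COMPLETION_EARLY:
            keep = trial.period_index <= 2
        elif stratum == COMPLETION_WITHDRAWAL:
            # drop out at a uniform week inside the first experimental
            # period (>= 1 experimental measurement kept); truncating
            # within period 1 keeps the generated label identical to the
            # observed-data completion classifier, which cannot tell a
            # mid-second-period withdrawal from an early completer
            exp1 = np.flatnonzero(trial.period_index == 1)
            last = exp1[int(rng.integers(0, len(exp1)))]
            keep = np.arange(trial.n) <= last
        t2 = TrialDataset(
            individual_id=ind,
            time=trial.time[keep],
            treatment=trial.treatment[keep],
            value=trial.value[keep],
            period_index=trial.period_index[keep],
            K=K,
            outcome_bounds=bounds,
            sequence_label=seq,
        )
        if dropout.mar_rate > 0.0:
            gaps = rng.random(t2.n) < dropout.mar_rate
            # never blank every measurement
            if gaps.all():
                gaps[int(rng.integers(0, t2.n))] = False
            v = t2.value.copy()
            v[gaps] = np.nan
            t2 = TrialDataset(
                individual_id=ind, time=t2.time, treatment=t2.treatment, value=v,
                period_index=t2.period_index, K=K, outcome_bounds=bounds, sequence_label=seq,
            )
        trials[ind] = t2
        truth.individual_params[ind] = {
            "mu": float(params.m),
            "delta": [float(x) for x in params.delta],
            "beta": float(params.beta),
            "rho_e": float(params.rho_e),
            "sigma": float(math.sqrt(params.sigma2)),
        }
        truth.strata[ind] = stratum
        truth.sequences[ind] = seq

    truth.n_truncated = int(sum(c for _, c in trunc))
    data = MultiTrialDataset(trials=trials, completion_stratum=dict(truth.strata))
    data.individual_covariates = pd.DataFrame(index=list(trials))
    return data, truth
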