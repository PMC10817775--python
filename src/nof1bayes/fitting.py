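"""Posterior assembly for a single N-of-1 trial.

Builds a :class:`~nof1bayes.mcmc.ComposedModel` for one trial under any
single-trial specification (arm or contrast mean, optional trend, AR(1)
errors or outcomes), with optional data augmentation of missing outcomes:
each missing slot becomes a state variable updated once per sweep from its
exact conditional normal, so parameter inference automatically averages
over the missing data (missing-at-random).
"""

from __future__ import annotations

import numpy as np

from .mcmc import ComposedModel, ParamSpec
from .missing import impute_mar_draw
from .priors import PriorSpec
from .single_trial import ModelSpec, SingleTrialParams, default_priors, loglik
from .trial_data import TrialDataset


def params_from_state(state: dict, spec: ModelSpec, K: int) -> SingleTrialParams:
    """Reconstruct a SingleTrialParams from named sampler state."""
    if spec.parameterization == "arm":
        m = np.array([state[f"m[{k}]"] for k in range(1, K + 1)])
        delta = None
    else:
        m = state["m"]
        delta = np.array([state[f"delta[{k}]"] for k in range(2, K + 1)])
    return SingleTrialParams(
        m=m,
        delta=delta,
        beta=state.get("beta", 0.0),
        rho_e=state.get("rho_e", 0.0),
        rho_Y=state.get("rho_Y", 0.0),
        sigma2=state.get("sigma", 1.0) ** 2,
    )


def assemble_single(
    trial: TrialDataset,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    impute: bool = False,
) -> ComposedModel:
    """Posterior log density for one trial, ready for the sampler.

    With ``impute=True`` every missing design slot gets a state variable
    ``ymis[<week>]`` drawn by data augmentation each sweep; the
    likelihood is then the complete-data likelihood.  Otherwise missing
    rows are skipped and the observed-data likelihood is used.
    """
    if trial.n_observed == 0:
        raise ValueError(f"{trial.individual_id}: no observed outcomes")
    if priors is None:
        priors = default_priors(spec, trial.outcome_bounds)

    model = ComposedModel()
    model.meta = {"individual_id": trial.individual_id, "K": trial.K, "spec": spec.to_dict()}
    obs_mean = float(np.mean(trial.value[trial.observed]))
    obs_sd = float(np.std(trial.value[trial.observed])) or 1.0

    names: list[str] = []
    if spec.parameterization == "arm":
        for k in range(1, trial.K + 1):
            name = f"m[{k}]"
            sel = trial.observed & (trial.treatment == k)
            init = float(np.mean(trial.value[sel])) if sel.any() else obs_mean
            lo, hi = priors[name].support
            init = min(max(init, lo + 1e-3), hi - 1e-3) if np.isfinite(lo) else init
            model.add_param(ParamSpec(name, init, lo, hi, kind="gaussian"))
            names.append(name)
    else:
        lo, hi = priors["m"].support
        init = min(max(obs_mean, lo + 1e-3), hi - 1e-3) if np.isfinite(lo) else obs_mean
        model.add_param(ParamSpec("m", init, lo, hi, kind="gaussian"))
        names.append("m")
        for k in range(2, trial.K + 1):
            name = f"delta[{k}]"
            model.add_param(ParamSpec(name, 0.0, *priors[name].support, kind="gaussian"))
            names.append(name)
    if spec.trend == "linear":
        model.add_param(ParamSpec("beta", 0.0, *priors["beta"].support, kind="gaussian"))
        names.append("beta")
    if spec.autocorrelation == "ar_errors":
        model.add_param(ParamSpec("rho_e", 0.0, -0.999, 0.999, kind="rw_atanh", step=0.3))
        names.append("rho_e")
    elif spec.autocorrelation == "ar_outcomes":
        model.add_param(ParamSpec("rho_Y", 0.0, -0.999, 0.999, kind="rw_atanh", step=0.3))
        names.append("rho_Y")
    if spec.family == "normal":
        model.add_param(
            ParamSpec("sigma", obs_sd, 1e-6, priors["sigma"].support[1], kind="rw_log", step=0.2)
        )
        names.append("sigma")
    for n in names:
        prior = priors[n]
        model.add_term(lambda s, p=prior, n=n: p.logpdf(s[n]), [n])

    missing_idx = np.flatnonzero(~trial.observed)
    if impute and missing_idx.size:
        mis_names = {int(j): f"ymis[{trial.time[j]:g}]" for j in missing_idx}
        for j, n in mis_names.items():
            model.extra_state[n] = obs_mean

        def lik_term(state, trial=trial, spec=spec, mis=mis_names):
            filled = trial.value.copy()
            for j, n in mis.items():
                filled[j] = state[n]
            from dataclasses import replace

            full = replace(trial, value=filled)
            return loglik(params_from_state(state, spec, trial.K), spec, full)

        model.add_term(lik_term, names)

        def augment(state, rng, trial=trial, spec=spec, mis=mis_names):
            params = params_from_state(state, spec, trial.K)
            filled = trial.value.copy()
            for j, n in mis.items():
                filled[j] = state[n]
            # refresh each missing slot from its conditional given the rest
            from dataclasses import replace

            base = replace(trial, value=trial.value)
            new = impute_mar_draw(base, params, spec, rng, filled=filled)
            for j, n in mis.items():
                state[n] = float(new[j])

        model.add_custom_update(augment)
    else:

        def lik_term(state, trial=trial, spec=spec):
            return loglik(params_from_state(state, spec, trial.K), spec, trial)

        model.add_term(lik_term, names)

    return model
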