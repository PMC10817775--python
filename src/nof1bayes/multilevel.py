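"""Multilevel (meta-analysis) models for collections of N-of-1 trials.

Each individual i contributes a first-level trial model

    y_ij = mu_i + sum_{k != 1} delta_ik I(A_ij = k) + beta_i t_ij + e_ij,

with AR(1) errors as in :mod:`nof1bayes.single_trial`.  The second level ties
the first-level parameters together.  Every parameter family (intercepts,
treatment effects, trend slopes, error correlations, residual variances)
can be treated as

``common``  one shared value across individuals,
``fixed``   a free value per individual, unrelated across individuals,
``random``  per-individual values drawn from a population distribution,
            e.g. delta_ik ~ N(d_k, sigma_delta^2), whose mean and variance
            (the hyperparameters) are themselves estimated.

Error correlations modeled as random effects are first mapped to the real
line by the Fisher-z (inverse hyperbolic tangent) transform.  Random
intercepts and effects may be correlated through the structured covariance
built by :func:`build_sigma_mu_delta`: because within a trial all treatment
contrasts share the reference arm and (under a constant treatment variance)
must have equal variance, the correlation between any two contrast random
effects is exactly 0.5.

Population treatment-effect means can be regressed on individual-level
covariates (d_k = d0_k + sum_j dj_k x_ij), enabling subgroup contrasts,
and within-individual covariates (e.g. an exponentially decaying carryover
indicator) enter the first-level mean with common or per-individual
coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mcmc import ComposedModel, ParamSpec, PosteriorDraws
from .priors import PriorSpec, normal, uniform
from .single_trial import (
    LOG2PI,
    STATIONARY_PRODUCT,
    ModelSpec,
    ar1_exact_loglik,
    ar1_outcome_loglik,
    ar1_stationary_product_loglik,
)
from .trial_data import MultiTrialDataset, TrialDataset

TREATMENTS = ("common", "fixed", "random")


@dataclass(frozen=True)
class HyperParams:
    """Second-level (population) parameter values, mainly for simulation.

    ``d`` are the population mean treatment contrasts d_k (k = 2..K);
    ``sigma_delta`` the between-individual SD of the contrasts; ``m`` and
    ``sigma_mu`` the mean and SD of the intercepts; ``b``/``sigma_beta``
    of the trend slopes; ``ze``/``sigma_ze`` of the Fisher-z transformed
    error correlations; ``rho_mu_delta`` the intercept-effect correlation;
    ``sigma`` the common residual (innovation) SD.
    """

    d: tuple[float, ...] = (-3.0,)
    sigma_delta: float = 2.0
    m: float = 55.0
    sigma_mu: float = 5.0
    b: float = 0.0
    sigma_beta: float = 0.0
    ze: float = 0.42
    sigma_ze: float = 0.0
    rho_mu_delta: float = 0.0
    sigma: float = 5.0

    @property
    def K(self) -> int:
        return len(self.d) + 1


@dataclass
class LevelSpec:
    """How each first-level parameter family is treated across individuals."""

    intercepts: str = "fixed"
    effects: str = "random"
    trend: str = "common"
    correlations: str = "common"
    residual: str = "common"
    correlation_structure: str = "independent"  # | "mu_delta_correlated"
    effect_covariates: list[str] = field(default_factory=list)
    within_covariates: list[str] = field(default_factory=list)
    within_coefficient: str = "common"  # | "fixed"

    def __post_init__(self) -> None:
        for attr in ("intercepts", "effects", "trend", "correlations"):
            if getattr(self, attr) not in TREATMENTS:
                raise ValueError(f"{attr} must be one of {TREATMENTS}")
        if self.residual not in ("common", "fixed"):
            raise ValueError("residual variances may only be common or fixed")
        if self.correlation_structure not in ("independent", "mu_delta_correlated"):
            raise ValueError("unknown correlation_structure")
        if self.correlation_structure == "mu_delta_correlated" and (
            self.intercepts != "random" or self.effects != "random"
        ):
            raise ValueError(
                "mu_delta_correlated requires random intercepts and random effects"
            )

    def to_dict(self) -> dict:
        return {
            "intercepts": self.intercepts,
            "effects": self.effects,
            "trend": self.trend,
            "correlations": self.correlations,
            "residual": self.residual,
            "correlation_structure": self.correlation_structure,
            "effect_covariates": list(self.effect_covariates),
            "within_covariates": list(self.within_covariates),
            "within_coefficient": self.within_coefficient,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LevelSpec":
        return cls(**d)


# ---------------------------------------------------------------------------
# structured intercept-effect covariance
# ---------------------------------------------------------------------------

def max_rho_mu_delta(K: int) -> float:
    """Largest |rho_mu_delta| keeping the structured covariance positive definite.

    With the contrast block fixed at correlation 0.5, positive definiteness
    requires rho^2 * 1' P^{-1} 1 < 1, i.e.
    |rho| < sqrt((1 + 0.5 (K - 2)) / (K - 1)).
    """
    q = K - 1
    return math.sqrt((1.0 + 0.5 * (q - 1)) / q)


def build_sigma_mu_delta(
    sigma_mu: float, sigma_delta: float, rho_mu_delta: float, K: int
) -> np.ndarray:
    """Covariance of the random vector (mu_i, delta_i2, ..., delta_iK).

    Top-left entry sigma_mu^2; the first row/column carries the common
    intercept-effect covariance rho * sigma_mu * sigma_delta; the
    contrast block is sigma_delta^2 * P(0.5) with unit diagonal and 0.5
    off-diagonals, the correlation forced by contrast consistency under a
    constant treatment variance.  The result is checked to be symmetric
    positive definite.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if sigma_mu <= 0 or sigma_delta <= 0:
        raise ValueError("standard deviations must be positive")
    q = K - 1
    S = np.empty((q + 1, q + 1))
    S[0, 0] = sigma_mu**2
    S[0, 1:] = S[1:, 0] = rho_mu_delta * sigma_mu * sigma_delta
    P = np.full((q, q), 0.5)
    np.fill_diagonal(P, 1.0)
    S[1:, 1:] = sigma_delta**2 * P
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"covariance not positive definite: |rho_mu_delta| must be below "
            f"{max_rho_mu_delta(K):.6f} for K={K}"
        ) from None
    return S


def fisher_z(rho: float) -> float:
    """Fisher-z (inverse hyperbolic tangent): z = 0.5 ln((1+rho)/(1-rho))."""
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    return math.atanh(rho)


def inv_fisher_z(z: float) -> float:
    """Inverse map back to (-1, 1): rho = (e^{2z} - 1) / (e^{2z} + 1).

    Large |z| would round to exactly +/-1 in floating point; the result is
    nudged to the nearest representable value inside the open interval.
    """
    r = math.tanh(z)
    if r >= 1.0:
        return math.nextafter(1.0, 0.0)
    if r <= -1.0:
        return math.nextafter(-1.0, 0.0)
    return r


# ---------------------------------------------------------------------------
# carryover
# ---------------------------------------------------------------------------

def carryover_covariate(t: float, t_star: float, half_life: float = 1.0) -> float:
    """Exponentially decaying carryover covariate 2^{-(t - t*)/half_life}.

    ``t_star`` is the crossover time; the covariate is 1 at the crossover
    instant and halves every ``half_life`` time units.
    """
    if half_life <= 0:
        raise ValueError("half_life must be > 0")
    if t < t_star:
        raise ValueError(f"t={t} precedes the crossover time t*={t_star}")
    return 2.0 ** (-(t - t_star) / half_life)


def total_effect(delta: float, z: float) -> float:
    """Total effect delta * (1 + z) when a treatment carries into placebo."""
    return delta * (1.0 + z)


def check_carryover_identifiable(trial: TrialDataset, covariate: np.ndarray) -> bool:
    """Rank check: is a carryover covariate separable from the design?

    Builds the first-level design matrix (intercept, treatment indicators,
    carryover column) and reports whether it has full column rank.  In
    repeating sequences (ABAB) the carryover column can be collinear with
    the sequence structure, in which case the effect is confounded and
    should not be fit.
    """
    obs = trial.observed
    cols = [np.ones(obs.sum())]
    for k in range(2, trial.K + 1):
        cols.append((trial.treatment[obs] == k).astype(float))
    cols.append(np.asarray(covariate, float)[obs])
    X = np.column_stack(cols)
    return int(np.linalg.matrix_rank(X, tol=1e-8)) == X.shape[1]


# ---------------------------------------------------------------------------
# default priors for the meta-analysis
# ---------------------------------------------------------------------------

def default_meta_priors(bounds: tuple[float, float]) -> PriorSpec:
    """Noninformative meta-analysis priors on a bounded outcome scale.

    Individual intercepts Uniform(lower, upper); population contrasts
    Uniform(-width, width); correlations Uniform(-1, 1); residual and
    between-individual SDs Uniform(0, 1000); trend parameters flat normal.
    """
    lo, hi = float(bounds[0]), float(bounds[1])
    w = hi - lo
    ps = PriorSpec()
    ps["mu"] = uniform(lo, hi)
    ps["m"] = uniform(lo, hi)
    ps["d"] = uniform(-w, w)
    ps["d0"] = uniform(-w, w)
    ps["delta"] = uniform(-w, w)
    ps["rho_e"] = uniform(-1.0, 1.0)
    ps["rho_mu_delta"] = uniform(-1.0, 1.0)
    ps["sigma"] = uniform(0.0, 1000.0)
    ps["sigma_delta"] = uniform(0.0, 1000.0)
    ps["sigma_mu"] = uniform(0.0, 1000.0)
    ps["sigma_beta"] = uniform(0.0, 1000.0)
    ps["sigma_ze"] = uniform(0.0, 1000.0)
    ps["b"] = normal(0.0, 1e6)
    ps["beta"] = normal(0.0, 1e6)
    ps["ze_mean"] = normal(0.0, 1e6)
    ps["ze"] = normal(0.0, 1e6)
    ps["gamma"] = normal(0.0, 1e6)
    return ps


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

def _norm_logpdf(x: float, mean: float, var: float) -> float:
    return -0.5 * ((x - mean) ** 2 / var + math.log(var) + LOG2PI)


def _trial_cache(trial: TrialDataset):
    """Precompute observed arrays and treatment indicators for fast loglik."""
    obs = trial.observed
    y = trial.value[obs]
    t = trial.time[obs]
    a = trial.treatment[obs]
    dt = np.empty_like(t)
    if len(t):
        dt[0] = 0.0
        dt[1:] = np.diff(t)
    ind = {k: (a == k).astype(float) for k in range(2, trial.K + 1)}
    return y, t, dt, ind


def _add_prior_term(model: ComposedModel, priors: PriorSpec, name: str) -> None:
    prior = priors[name]
    model.add_term(lambda s, p=prior, n=name: p.logpdf(s[n]), [name])


def _mean_init(trial: TrialDataset) -> float:
    obs = trial.observed
    ref = obs & (trial.treatment == 1)
    if ref.any():
        return float(np.mean(trial.value[ref]))
    return float(np.mean(trial.value[obs]))


def _clip_to(prior, x: float) -> float:
    lo, hi = prior.support
    if lo > -math.inf and hi < math.inf:
        pad = 1e-3 * (hi - lo)
        return float(min(max(x, lo + pad), hi - pad))
    return x


def assemble_multilevel(
    data: MultiTrialDataset,
    spec: ModelSpec,
    level: LevelSpec,
    priors: PriorSpec | None = None,
) -> ComposedModel:
    """Build the joint posterior log density of the multilevel model.

    The parameter vector contains every first-level parameter that is
    fixed or random (named ``mu[i]``, ``delta[i,k]``, ...), shared values
    for common families (``mu``, ``d[k]``, ``rho_e``, ``sigma``), and the
    hyperparameters of each random family (``d[k]``/``sigma_delta``,
    ``m``/``sigma_mu``, ``b``/``sigma_beta``, ``ze_mean``/``sigma_ze``,
    ``rho_mu_delta``).  The log density is the sum of the first-level
    log-likelihoods, the random-effect log densities, and the priors.
    """
    if spec.parameterization != "contrast":
        raise ValueError("the multilevel model uses the contrast parameterization")
    if not data.trials:
        raise ValueError("no trials in dataset")
    ids = data.ids
    K = next(iter(data.trials.values())).K
    for trial in data.trials.values():
        if trial.K != K:
            raise ValueError("all trials must share the same treatment set")
        if trial.n_observed == 0:
            raise ValueError(f"{trial.individual_id}: no observed outcomes")
    if level.effect_covariates:
        data.require_covariates(level.effect_covariates)

    bounds = next(iter(data.trials.values())).outcome_bounds
    if priors is None:
        priors = default_meta_priors(bounds)

    model = ComposedModel()
    model.meta = {
        "ids": ids,
        "K": K,
        "spec": spec.to_dict(),
        "level": level.to_dict(),
    }
    caches = {i: _trial_cache(data.trials[i]) for i in ids}
    pooled_sd = float(
        np.std(np.concatenate([caches[i][0] for i in ids]))
    ) or 1.0

    # ---- parameter names per individual -------------------------------
    mu_name = {}
    delta_names = {}
    beta_name = {}
    rho_name = {}
    sigma_name = {}

    # intercepts
    if level.intercepts == "common":
        model.add_param(
            ParamSpec("mu", _clip_to(priors["mu"], float(np.mean([_mean_init(data.trials[i]) for i in ids]))),
                      *priors["mu"].support, kind="gaussian")
        )
        _add_prior_term(model, priors, "mu")
        for i in ids:
            mu_name[i] = "mu"
    else:
        for i in ids:
            name = f"mu[{i}]"
            model.add_param(
                ParamSpec(name, _clip_to(priors[name], _mean_init(data.trials[i])),
                          *priors[name].support, kind="gaussian")
            )
            mu_name[i] = name
            if level.intercepts == "fixed":
                _add_prior_term(model, priors, name)

    # treatment effects + hyper-regression on individual covariates
    cov_names = list(level.effect_covariates)
    if level.effects == "common":
        for k in range(2, K + 1):
            name = f"d[{k}]"
            model.add_param(ParamSpec(name, 0.0, *priors[name].support, kind="gaussian"))
            _add_prior_term(model, priors, name)
        for i in ids:
            delta_names[i] = {k: f"d[{k}]" for k in range(2, K + 1)}
    else:
        for i in ids:
            delta_names[i] = {}
            for k in range(2, K + 1):
                name = f"delta[{i},{k}]"
                model.add_param(ParamSpec(name, 0.0, *priors[name].support, kind="gaussian"))
                delta_names[i][k] = name
                if level.effects == "fixed":
                    _add_prior_term(model, priors, name)
        if level.effects == "random":
            dmean_names: dict[int, list[str]] = {}
            for k in range(2, K + 1):
                base = f"d[{k}]" if not cov_names else f"d0[{k}]"
                model.add_param(ParamSpec(base, 0.0, *priors[base].support, kind="gaussian"))
                _add_prior_term(model, priors, base)
                dmean_names[k] = [base]
                for cov in cov_names:
                    cname = f"d_{cov}[{k}]"
                    model.add_param(ParamSpec(cname, 0.0, *priors[cname].support, kind="gaussian"))
                    _add_prior_term(model, priors, cname)
                    dmean_names[k].append(cname)
            model.add_param(
                ParamSpec("sigma_delta", 1.0, 1e-6, priors["sigma_delta"].support[1], kind="rw_log")
            )
            _add_prior_term(model, priors, "sigma_delta")

    # trend
    if spec.trend == "linear":
        if level.trend == "common":
            model.add_param(ParamSpec("beta", 0.0, *priors["beta"].support, kind="gaussian"))
            _add_prior_term(model, priors, "beta")
            for i in ids:
                beta_name[i] = "beta"
        else:
            for i in ids:
                name = f"beta[{i}]"
                model.add_param(ParamSpec(name, 0.0, *priors[name].support, kind="gaussian"))
                beta_name[i] = name
                if level.trend == "fixed":
                    _add_prior_term(model, priors, name)
            if level.trend == "random":
                model.add_param(ParamSpec("b", 0.0, *priors["b"].support, kind="gaussian"))
                _add_prior_term(model, priors, "b")
                model.add_param(
                    ParamSpec("sigma_beta", 0.5, 1e-6, priors["sigma_beta"].support[1], kind="rw_log")
                )
                _add_prior_term(model, priors, "sigma_beta")

    # error autocorrelation
    if spec.autocorrelation == "ar_errors":
        if level.correlations == "common":
            model.add_param(ParamSpec("rho_e", 0.0, -0.999, 0.999, kind="rw_atanh", step=0.3))
            _add_prior_term(model, priors, "rho_e")
            for i in ids:
                rho_name[i] = ("rho", "rho_e")
        elif level.correlations == "fixed":
            for i in ids:
                name = f"rho_e[{i}]"
                model.add_param(ParamSpec(name, 0.0, -0.999, 0.999, kind="rw_atanh", step=0.3))
                _add_prior_term(model, priors, name)
                rho_name[i] = ("rho", name)
        else:  # random on Fisher-z scale
            for i in ids:
                name = f"ze[{i}]"
                model.add_param(ParamSpec(name, 0.0, kind="rw", step=0.3))
                rho_name[i] = ("ze", name)
            model.add_param(ParamSpec("ze_mean", 0.0, kind="gaussian"))
            _add_prior_term(model, priors, "ze_mean")
            model.add_param(
                ParamSpec("sigma_ze", 0.3, 1e-6, priors["sigma_ze"].support[1], kind="rw_log")
            )
            _add_prior_term(model, priors, "sigma_ze")
    else:
        for i in ids:
            rho_name[i] = ("none", None)

    # residual SD
    if level.residual == "common":
        model.add_param(
            ParamSpec("sigma", pooled_sd, 1e-6, priors["sigma"].support[1], kind="rw_log", step=0.2)
        )
        _add_prior_term(model, priors, "sigma")
        for i in ids:
            sigma_name[i] = "sigma"
    else:
        for i in ids:
            name = f"sigma[{i}]"
            model.add_param(
                ParamSpec(name, pooled_sd, 1e-6, priors[name].support[1], kind="rw_log", step=0.2)
            )
            _add_prior_term(model, priors, name)
            sigma_name[i] = name

    # within-individual covariates (gamma_li * z_lij terms), e.g. carryover
    gamma_names: dict[str, dict[str, str]] = {i: {} for i in ids}
    wc = data.within_covariates
    if level.within_covariates:
        if wc is None:
            raise ValueError("within_covariates requested but none provided in data")
        for covname in level.within_covariates:
            if covname not in wc.columns:
                raise ValueError(f"within covariate {covname!r} not in data")
            if level.within_coefficient == "common":
                gname = f"gamma_{covname}"
                model.add_param(ParamSpec(gname, 0.0, *priors[gname].support, kind="gaussian"))
                _add_prior_term(model, priors, gname)
                for i in ids:
                    gamma_names[i][covname] = gname
            else:
                for i in ids:
                    gname = f"gamma_{covname}[{i}]"
                    model.add_param(ParamSpec(gname, 0.0, *priors[gname].support, kind="gaussian"))
                    _add_prior_term(model, priors, gname)
                    gamma_names[i][covname] = gname

    # ---- first-level likelihood terms ---------------------------------
    mode = spec.likelihood_mode
    for i in ids:
        y, t, dt, ind = caches[i]
        kinds = sorted(ind)
        ind_mat = np.array([ind[k] for k in kinds]) if kinds else np.zeros((0, len(y)))
        dnames = [delta_names[i][k] for k in kinds]
        rkind, rname = rho_name[i]
        sname = sigma_name[i]
        mname = mu_name[i]
        bname = beta_name.get(i)
        gnames = gamma_names[i]
        gcols = {}
        if gnames:
            sub = wc[wc["id"].astype(str) == str(i)].set_index("time")
            for covname in gnames:
                gcols[covname] = sub.loc[t, covname].to_numpy(float)

        deps = [mname, sname] + dnames + list(gnames.values())
        if bname:
            deps.append(bname)
        if rname:
            deps.append(rname)

        def term(
            state,
            y=y,
            t=t,
            dt=dt,
            ind_mat=ind_mat,
            dnames=dnames,
            mname=mname,
            bname=bname,
            rkind=rkind,
            rname=rname,
            sname=sname,
            gnames=gnames,
            gcols=gcols,
            mode=mode,
            auto=spec.autocorrelation,
        ):
            mean = state[mname] + (
                np.array([state[n] for n in dnames]) @ ind_mat if dnames else 0.0
            )
            if bname:
                mean = mean + state[bname] * t
            for covname, gname in gnames.items():
                mean = mean + state[gname] * gcols[covname]
            sig2 = state[sname] ** 2
            if auto == "ar_errors":
                rho = state[rname] if rkind == "rho" else math.tanh(state[rname])
                if mode == STATIONARY_PRODUCT:
                    return ar1_stationary_product_loglik(y, mean, rho, sig2)
                return ar1_exact_loglik(y, mean, rho, sig2, dt)
            if auto == "ar_outcomes":
                raise NotImplementedError(
                    "multilevel ar_outcomes models are not supported"
                )
            dev = y - mean
            return -0.5 * float(np.sum(LOG2PI + math.log(sig2) + dev**2 / sig2))

        model.add_term(term, deps)

    # ---- random-effect terms ------------------------------------------
    xcov = None
    if cov_names:
        xcov = data.individual_covariates.loc[ids, cov_names]

    if level.correlation_structure == "mu_delta_correlated":
        model.add_param(
            ParamSpec("rho_mu_delta", 0.0, -0.999, 0.999, kind="rw_atanh", step=0.3)
        )
        _add_prior_term(model, priors, "rho_mu_delta")
        model.add_param(ParamSpec("m", _clip_to(priors["m"], float(np.mean([_mean_init(data.trials[i]) for i in ids]))),
                                  *priors["m"].support, kind="gaussian"))
        _add_prior_term(model, priors, "m")
        model.add_param(ParamSpec("sigma_mu", pooled_sd, 1e-6, priors["sigma_mu"].support[1], kind="rw_log"))
        _add_prior_term(model, priors, "sigma_mu")

        for i in ids:
            names = [mu_name[i]] + [delta_names[i][k] for k in range(2, K + 1)]
            mean_names = ["m"] + [
                dmean_names[k] for k in range(2, K + 1)
            ]
            deps = list(names) + ["m", "sigma_mu", "sigma_delta", "rho_mu_delta"]
            for k in range(2, K + 1):
                deps += dmean_names[k]
            xrow = xcov.loc[i].to_numpy(float) if xcov is not None else None

            def re_term(state, names=names, mean_names=mean_names, xrow=xrow, K=K):
                try:
                    S = build_sigma_mu_delta(
                        state["sigma_mu"], state["sigma_delta"], state["rho_mu_delta"], K
                    )
                except ValueError:
                    return -math.inf
                v = np.array([state[n] for n in names])
                mvec = [state["m"]]
                for k in range(2, K + 1):
                    parts = mean_names[k - 1]
                    mk = state[parts[0]]
                    if xrow is not None:
                        mk += float(
                            np.dot([state[p] for p in parts[1:]], xrow)
                        )
                    mvec.append(mk)
                dev = v - np.array(mvec)
                L = np.linalg.cholesky(S)
                sol = np.linalg.solve(L, dev)
                return float(
                    -0.5 * (sol @ sol) - np.log(np.diag(L)).sum() - 0.5 * len(v) * LOG2PI
                )

            model.add_term(re_term, deps)
    else:
        # independent random-effect families
        if level.intercepts == "random":
            model.add_param(ParamSpec("m", _clip_to(priors["m"], float(np.mean([_mean_init(data.trials[i]) for i in ids]))),
                                      *priors["m"].support, kind="gaussian"))
            _add_prior_term(model, priors, "m")
            model.add_param(ParamSpec("sigma_mu", pooled_sd, 1e-6, priors["sigma_mu"].support[1], kind="rw_log"))
            _add_prior_term(model, priors, "sigma_mu")
            for i in ids:
                model.add_term(
                    lambda s, n=mu_name[i]: _norm_logpdf(s[n], s["m"], s["sigma_mu"] ** 2),
                    [mu_name[i], "m", "sigma_mu"],
                )
        if level.effects == "random":
            for i in ids:
                xrow = xcov.loc[i].to_numpy(float) if xcov is not None else None
                for k in range(2, K + 1):
                    parts = dmean_names[k]
                    deps = [delta_names[i][k], "sigma_delta"] + parts

                    def eff_term(state, n=delta_names[i][k], parts=parts, xrow=xrow):
                        mk = state[parts[0]]
                        if xrow is not None:
                            mk += float(np.dot([state[p] for p in parts[1:]], xrow))
                        return _norm_logpdf(state[n], mk, state["sigma_delta"] ** 2)

                    model.add_term(eff_term, deps)

    if spec.trend == "linear" and level.trend == "random":
        for i in ids:
            model.add_term(
                lambda s, n=beta_name[i]: _norm_logpdf(s[n], s["b"], s["sigma_beta"] ** 2),
                [beta_name[i], "b", "sigma_beta"],
            )
    if spec.autocorrelation == "ar_errors" and level.correlations == "random":
        for i in ids:
            _, zn = rho_name[i]
            model.add_term(
                lambda s, n=zn: _norm_logpdf(s[n], s["ze_mean"], s["sigma_ze"] ** 2),
                [zn, "ze_mean", "sigma_ze"],
            )

    model.meta["mu_names"] = mu_name
    model.meta["delta_names"] = {i: dict(delta_names[i]) for i in ids}
    return model


# ---------------------------------------------------------------------------
# subgroup effects
# ---------------------------------------------------------------------------

def subgroup_effect(
    draws: PosteriorDraws,
    k: int,
    setting_a: dict[str, float],
    setting_b: dict[str, float],
) -> dict[str, np.ndarray]:
    """Posterior draws of the population effect d_k at two covariate settings.

    Returns arrays ``a``, ``b`` (per-draw linear combinations
    d0_k + sum_j dj_k x_j at each setting) and ``difference`` (a - b),
    ready for probability statements such as P(effect larger in group a).
    """
    base = f"d0[{k}]" if f"d0[{k}]" in draws.draws else f"d[{k}]"
    if base not in draws.draws:
        raise ValueError(f"no population effect parameter for treatment {k}")
    out_a = draws.stacked(base).copy()
    out_b = draws.stacked(base).copy()
    for cov in set(setting_a) | set(setting_b):
        cname = f"d_{cov}[{k}]"
        if cname not in draws.draws:
            raise ValueError(f"unknown covariate coefficient {cname!r} in draws")
        coef = draws.stacked(cname)
        out_a = out_a + coef * float(setting_a.get(cov, 0.0))
        out_b = out_b + coef * float(setting_b.get(cov, 0.0))
    return {"a": out_a, "b": out_b, "difference": out_a - out_b}
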