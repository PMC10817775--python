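"""Model specification and log-likelihood evaluation for one N-of-1 trial.

The outcome series of a single trial is modeled as

    Y_j = mean structure + error,

where the mean structure is either *contrast-based* (a reference-treatment
mean m plus treatment contrasts delta_k for k = 2..K) or *arm-based*
(one mean m_k per treatment arm), optionally with a linear time trend
beta * t_j.  Errors are i.i.d. normal, AR(1)-autocorrelated
(e_j = rho_e e_{j-1} + eps_j), or the outcomes themselves follow an AR(1)
(Y_j depends on rho_Y * Y_{j-1}).  Discrete outcomes use a Bernoulli-logit
or Poisson-log generalized linear model with the same linear predictor.

Two likelihood modes are provided for the AR(1)-errors model.  ``exact``
(the default) is the joint density obtained from the conditional AR(1)
decomposition: the first observation from its stationary marginal
N(M_1, sigma^2/(1-rho^2)) and each later observation conditionally normal
given the previous one.  ``stationary_product`` multiplies the stationary
marginals N(M_j, sigma^2/(1-rho^2)) as if observations were independent;
it is retained because some presentations of the model write the
likelihood in that product form, but it discards the cross-time
correlation and is not recommended for inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .priors import Prior, PriorSpec, normal, uniform
from .trial_data import TrialDataset

LOG2PI = math.log(2.0 * math.pi)

#: Literal product-of-stationary-marginals likelihood (not the exact joint).
STATIONARY_PRODUCT = "stationary_product"


@dataclass(frozen=True)
class ModelSpec:
    """Which model components are active and how the mean is parameterized.

    Attributes
    ----------
    parameterization : {"contrast", "arm"}
    trend : {"none", "linear"}
    autocorrelation : {"none", "ar_errors", "ar_outcomes"}
    family : {"normal", "bernoulli_logit", "poisson_log"}
    carryover : {"none", "half_life"}
    likelihood_mode : {"exact", "stationary_product"}
    """

    parameterization: str = "contrast"
    trend: str = "none"
    autocorrelation: str = "none"
    family: str = "normal"
    carryover: str = "none"
    likelihood_mode: str = "exact"

    def __post_init__(self) -> None:
        allowed = {
            "parameterization": {"contrast", "arm"},
            "trend": {"none", "linear"},
            "autocorrelation": {"none", "ar_errors", "ar_outcomes"},
            "family": {"normal", "bernoulli_logit", "poisson_log"},
            "carryover": {"none", "half_life"},
            "likelihood_mode": {"exact", STATIONARY_PRODUCT},
        }
        for attr, ok in allowed.items():
            if getattr(self, attr) not in ok:
                raise ValueError(f"{attr}={getattr(self, attr)!r} not in {sorted(ok)}")
        if self.family != "normal" and self.autocorrelation != "none":
            raise ValueError(
                "discrete families require autocorrelation='none' "
                "(no latent-variable autocorrelation model is provided)"
            )

    def to_dict(self) -> dict:
        return {
            "parameterization": self.parameterization,
            "trend": self.trend,
            "autocorrelation": self.autocorrelation,
            "family": self.family,
            "carryover": self.carryover,
            "likelihood_mode": self.likelihood_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


@dataclass
class SingleTrialParams:
    """Parameter values for one trial.

    ``m`` is the reference-treatment mean in contrast form, or an array of
    K arm means in arm form.  ``delta`` holds the contrasts delta_k for
    k = 2..K (contrast form only).  ``sigma2`` is the innovation variance
    of the error process.
    """

    m: float | np.ndarray
    delta: np.ndarray | None = None
    beta: float = 0.0
    rho_e: float = 0.0
    rho_Y: float = 0.0
    sigma2: float = 1.0

    def validate(self, spec: ModelSpec) -> None:
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")
        if spec.autocorrelation == "ar_errors" and not abs(self.rho_e) < 1:
            raise ValueError(f"|rho_e| must be < 1, got {self.rho_e}")
        if spec.autocorrelation == "ar_outcomes" and not abs(self.rho_Y) < 1:
            raise ValueError(f"|rho_Y| must be < 1, got {self.rho_Y}")
        if spec.parameterization == "contrast" and np.ndim(self.m) != 0:
            raise ValueError("contrast parameterization needs a scalar reference mean")
        if spec.parameterization == "arm" and np.ndim(self.m) != 1:
            raise ValueError("arm parameterization needs one mean per treatment")


# ---------------------------------------------------------------------------
# linear predictor and marginal moments
# ---------------------------------------------------------------------------

def linear_predictor(
    params: SingleTrialParams,
    spec: ModelSpec,
    time: np.ndarray,
    treatment: np.ndarray,
) -> np.ndarray:
    """Mean structure M_j (before any autoregressive terms)."""
    time = np.asarray(time, dtype=float)
    treatment = np.asarray(treatment, dtype=int)
    if spec.parameterization == "arm":
        marm = np.asarray(params.m, dtype=float)
        mu = marm[treatment - 1]
    else:
        mu = np.full(time.shape, float(params.m))
        if params.delta is not None and len(params.delta):
            delta = np.asarray(params.delta, dtype=float)
            nonref = treatment > 1
            mu = mu + np.where(nonref, delta[np.clip(treatment - 2, 0, None)], 0.0)
    if spec.trend == "linear":
        mu = mu + params.beta * time
    return mu


def marginal_moments(
    params: SingleTrialParams, spec: ModelSpec, time: float, treatment: int
) -> tuple[float, float]:
    """Stationary marginal mean and variance of one measurement.

    Under AR(1) errors the stationary marginal is
    N(M_j, sigma^2 / (1 - rho_e^2)); without autocorrelation the variance
    is sigma^2.
    """
    if spec.family != "normal":
        raise ValueError("marginal_moments is defined for the normal family")
    if spec.autocorrelation == "ar_outcomes":
        raise ValueError("marginal_moments covers ar_errors or no autocorrelation")
    mean = float(linear_predictor(params, spec, np.array([time]), np.array([treatment]))[0])
    if spec.autocorrelation == "ar_errors":
        if not abs(params.rho_e) < 1:
            raise ValueError(f"nonstationary: |rho_e| >= 1 (rho_e={params.rho_e})")
        var = params.sigma2 / (1.0 - params.rho_e**2)
    else:
        var = params.sigma2
    return mean, var


# ---------------------------------------------------------------------------
# AR(1) log-likelihood kernels
# ---------------------------------------------------------------------------

def _lag_powers(rho: float, dt: np.ndarray) -> np.ndarray:
    """rho ** dt for positive lags dt (in weeks).

    Integer lags are always valid.  Non-integer lags require rho > 0
    (a real-valued power of a negative base is undefined).
    """
    dt = np.asarray(dt, dtype=float)
    near_int = np.all(np.abs(dt - np.round(dt)) < 1e-9)
    if near_int:
        return np.float_power(rho, np.round(dt)) if rho != 0 else np.where(dt > 0, 0.0, 1.0) ** 1
    if rho <= 0:
        raise ValueError("non-integer measurement gaps need rho > 0")
    return np.power(rho, dt)


def ar1_exact_loglik(
    y: np.ndarray, mean: np.ndarray, rho: float, sigma2: float, dt: np.ndarray
) -> float:
    """Exact joint log density of an AR(1)-error series observed at gaps ``dt``.

    ``dt[j]`` is the time gap (weeks) between observation j and j-1
    (dt[0] is ignored).  The first observation uses the stationary
    marginal; observation j given j-1 is normal with mean
    mean_j + rho^dt (y_{j-1} - mean_{j-1}) and variance
    sigma^2 (1 - rho^{2 dt}) / (1 - rho^2).  With unit gaps throughout
    this equals the dense multivariate normal with covariance
    sigma^2 rho^{|i-j|} / (1 - rho^2).
    """
    if not abs(rho) < 1:
        return -math.inf
    if sigma2 <= 0:
        return -math.inf
    n = len(y)
    svar = sigma2 / (1.0 - rho**2)  # stationary variance
    dev = y - mean
    if n == 1:
        return -0.5 * (LOG2PI + math.log(svar) + dev[0] ** 2 / svar)
    r = _lag_powers(rho, dt[1:])
    cond_var = svar * (1.0 - r**2)
    resid = dev[1:] - r * dev[:-1]
    ll = -0.5 * (LOG2PI + math.log(svar) + dev[0] ** 2 / svar)
    ll += -0.5 * float(np.sum(LOG2PI + np.log(cond_var) + resid**2 / cond_var))
    return ll


def ar1_stationary_product_loglik(
    y: np.ndarray, mean: np.ndarray, rho: float, sigma2: float
) -> float:
    """Product of stationary marginals N(M_j, sigma^2/(1-rho^2)).

    This treats the observations as independent draws from their common
    stationary marginal; it ignores cross-time correlation.
    """
    if not abs(rho) < 1 or sigma2 <= 0:
        return -math.inf
    svar = sigma2 / (1.0 - rho**2)
    dev = y - mean
    return -0.5 * float(np.sum(LOG2PI + math.log(svar) + dev**2 / svar))


def ar1_outcome_loglik(
    y: np.ndarray, lin: np.ndarray, rho_y: float, sigma2: float
) -> float:
    """Log density for the autocorrelated-outcomes model.

    Y_j = lin_j + rho_Y Y_{j-1} + eps_j.  The first observation is taken
    from its stationary marginal N(lin_1/(1-rho_Y), sigma^2/(1-rho_Y^2));
    later observations are conditionally N(lin_j + rho_Y y_{j-1}, sigma^2).
    Consecutive (unit-gap) measurements are assumed.
    """
    if not abs(rho_y) < 1 or sigma2 <= 0:
        return -math.inf
    ll = stats.norm.logpdf(
        y[0], loc=lin[0] / (1.0 - rho_y), scale=math.sqrt(sigma2 / (1.0 - rho_y**2))
    )
    if len(y) > 1:
        resid = y[1:] - lin[1:] - rho_y * y[:-1]
        ll += -0.5 * float(np.sum(LOG2PI + math.log(sigma2) + resid**2 / sigma2))
    return float(ll)


# ---------------------------------------------------------------------------
# public likelihood entry points
# ---------------------------------------------------------------------------

def loglik(params: SingleTrialParams, spec: ModelSpec, trial: TrialDataset) -> float:
    """Joint log density of the observed outcomes of one trial.

    Missing-outcome rows are skipped; under AR(1) errors the gap they
    leave is handled exactly through the lag-dependent conditionals.
    """
    params.validate(spec)
    if spec.family != "normal":
        return glm_loglik(params, spec, trial)
    obs = trial.observed
    if not obs.any():
        raise ValueError(f"{trial.individual_id}: no non-missing outcomes")
    y = trial.value[obs]
    if not np.all(np.isfinite(y)):
        raise ValueError(f"{trial.individual_id}: nonfinite outcome value")
    t = trial.time[obs]
    a = trial.treatment[obs]
    mean = linear_predictor(params, spec, t, a)

    if spec.autocorrelation == "none":
        if params.sigma2 <= 0:
            return -math.inf
        dev = y - mean
        return -0.5 * float(
            np.sum(LOG2PI + math.log(params.sigma2) + dev**2 / params.sigma2)
        )
    if spec.autocorrelation == "ar_errors":
        dt = np.empty_like(t)
        dt[0] = 0.0
        dt[1:] = np.diff(t)
        if spec.likelihood_mode == STATIONARY_PRODUCT:
            return ar1_stationary_product_loglik(y, mean, params.rho_e, params.sigma2)
        return ar1_exact_loglik(y, mean, params.rho_e, params.sigma2, dt)
    # ar_outcomes
    return ar1_outcome_loglik(y, mean, params.rho_Y, params.sigma2)


def glm_loglik(params: SingleTrialParams, spec: ModelSpec, trial: TrialDataset) -> float:
    """Log mass of discrete outcomes under a Bernoulli-logit or Poisson-log GLM."""
    obs = trial.observed
    y = trial.value[obs]
    eta = linear_predictor(params, spec, trial.time[obs], trial.treatment[obs])
    if spec.family == "bernoulli_logit":
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError(f"{trial.individual_id}: Bernoulli outcomes must be 0/1")
        # log p = y*eta - log(1 + e^eta), numerically stable via logaddexp
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    if spec.family == "poisson_log":
        if np.any(y < 0) or not np.all(y == np.round(y)):
            raise ValueError(f"{trial.individual_id}: Poisson outcomes must be counts")
        lam = np.exp(eta)
        return float(np.sum(stats.poisson.logpmf(y.astype(int), lam)))
    # identity-link normal: same as the normal-family likelihood
    return loglik(params, spec, trial)


# ---------------------------------------------------------------------------
# default priors
# ---------------------------------------------------------------------------

def default_priors(spec: ModelSpec, bounds: tuple[float, float]) -> PriorSpec:
    """Noninformative priors tailored to a bounded outcome scale.

    Treatment means get Uniform(lower, upper); contrasts get
    Uniform(-(upper-lower), upper-lower); correlations Uniform(-1, 1);
    the residual standard deviation Uniform(0, 1000); a trend slope
    Normal(0, 1e6).
    """
    lo, hi = float(bounds[0]), float(bounds[1])
    width = hi - lo
    ps = PriorSpec()
    if spec.parameterization == "arm":
        ps["m"] = uniform(lo, hi)
    else:
        ps["m"] = uniform(lo, hi)
        ps["delta"] = uniform(-width, width)
    ps["beta"] = normal(0.0, 1e6)
    ps["rho_e"] = uniform(-1.0, 1.0)
    ps["rho_Y"] = uniform(-1.0, 1.0)
    ps["sigma"] = uniform(0.0, 1000.0)
    return ps
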