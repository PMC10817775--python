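"""Metropolis-within-Gibbs sampler with convergence diagnostics.

The sampler operates on a :class:`ComposedModel`: a sum of log-density
*terms*, each depending on a declared subset of named parameters.  The
dependency structure lets each parameter update evaluate only the terms
that involve it, which is what makes systematic-scan Gibbs affordable for
multilevel models with one parameter block per individual.

Update rules per parameter kind:

``gaussian``
    Mean-type parameters whose full conditional is exactly Gaussian
    (every mean, contrast, trend and random-effect-mean parameter in the
    normal/AR(1) models here).  The conditional is identified exactly by
    probing the conditional log-density at three points and fitting the
    quadratic; the draw is from the implied normal truncated to the
    prior support.  This is a conjugate Gibbs step — no rejection beyond
    the support truncation.

``rw`` / ``rw_log`` / ``rw_atanh``
    Adaptive random-walk Metropolis on the given scale (identity, log
    for standard deviations, Fisher-z for correlations).  Step sizes
    adapt toward a 0.44 acceptance rate during warmup only, so the
    post-warmup chain is a fixed Markov kernel.

Custom updates (e.g. data augmentation of missing outcomes) may be
attached to the model and run once per sweep.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

logger = logging.getLogger("nof1bayes")

_SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# model description
# ---------------------------------------------------------------------------

@dataclass
class ParamSpec:
    """One named scalar parameter: support, update kind, initial value."""

    name: str
    init: float
    lower: float = -math.inf
    upper: float = math.inf
    kind: str = "gaussian"  # gaussian | rw | rw_log | rw_atanh
    step: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "rw", "rw_log", "rw_atanh"):
            raise ValueError(f"unknown update kind {self.kind!r}")
        if not self.lower <= self.init <= self.upper:
            raise ValueError(
                f"{self.name}: init {self.init} outside [{self.lower}, {self.upper}]"
            )


class ComposedModel:
    """A posterior log density assembled from dependency-tagged terms."""

    def __init__(self) -> None:
        self.params: list[ParamSpec] = []
        self._terms: list[tuple[Callable[[dict], float], frozenset[str]]] = []
        self._by_param: dict[str, list[int]] = {}
        self.custom_updates: list[Callable[[dict, np.random.Generator], None]] = []
        #: non-parameter state (e.g. augmented missing outcomes) and inits
        self.extra_state: dict[str, float] = {}
        self.meta: dict = {}

    def add_param(self, spec: ParamSpec) -> None:
        if spec.name in self._by_param:
            raise ValueError(f"duplicate parameter {spec.name!r}")
        self.params.append(spec)
        self._by_param[spec.name] = []

    def add_term(self, fn: Callable[[dict], float], names) -> None:
        names = frozenset(names)
        idx = len(self._terms)
        self._terms.append((fn, names))
        for n in names:
            if n in self._by_param:
                self._by_param[n].append(idx)

    def add_custom_update(self, fn: Callable[[dict, np.random.Generator], None]) -> None:
        self.custom_updates.append(fn)

    @property
    def param_names(self) -> list[str]:
        return [p.name for p in self.params]

    def init_state(self, init: dict | None = None) -> dict:
        state = {p.name: float(p.init) for p in self.params}
        state.update({k: float(v) for k, v in self.extra_state.items()})
        if init:
            unknown = set(init) - set(state)
            if unknown:
                raise ValueError(f"unknown init parameters: {sorted(unknown)}")
            state.update({k: float(v) for k, v in init.items()})
        return state

    def logpost(self, state: dict) -> float:
        return sum(fn(state) for fn, _ in self._terms)

    def cond_logpost(self, name: str, state: dict) -> float:
        """Sum only of the terms that depend on ``name``."""
        return sum(self._terms[i][0](state) for i in self._by_param[name])

    def pin_param(self, name: str, value: float) -> None:
        """Freeze a parameter at a fixed value (it leaves the sampled vector)."""
        match = [p for p in self.params if p.name == name]
        if not match:
            raise ValueError(f"no parameter {name!r} to pin")
        self.params = [p for p in self.params if p.name != name]
        del self._by_param[name]
        self.extra_state[name] = float(value)


# ---------------------------------------------------------------------------
# sampler configuration and output container
# ---------------------------------------------------------------------------

@dataclass
class SamplerConfig:
    chains: int = 4
    warmup: int = 2500
    draws: int = 2500
    seed: int = 0
    rhat_threshold: float = 1.05
    adapt_rate: float = 0.25  # Robbins-Monro exponent scale during warmup
    target_accept: float = 0.44

    def __post_init__(self) -> None:
        if self.chains < 1 or self.draws < 1 or self.warmup < 0:
            raise ValueError("need chains >= 1, draws >= 1, warmup >= 0")
        if self.rhat_threshold < 1:
            raise ValueError("rhat_threshold must be >= 1")


@dataclass
class PosteriorDraws:
    """Labeled posterior sample: parameter name -> (chains, draws) array."""

    draws: dict[str, np.ndarray]
    config: SamplerConfig | None = None
    model_meta: dict = field(default_factory=dict)
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated into one vector."""
        return self.draws[name].reshape(-1)

    def names(self) -> list[str]:
        return list(self.draws)

    def subset(self, names) -> "PosteriorDraws":
        return PosteriorDraws(
            {n: self.draws[n] for n in names}, self.config, self.model_meta, self.acceptance
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: chain, draw, parameter, value."""
        frames = []
        for name, arr in self.draws.items():
            c, d = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), d),
                        "draw": np.tile(np.arange(d), c),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_inferencedata(self):
        """Convert to an ArviZ InferenceData (requires arviz)."""
        import arviz as az

        return az.from_dict({k: v for k, v in self.draws.items()})


# ---------------------------------------------------------------------------
# truncated-normal draw via inverse CDF (exact, no rejection loop)
# ---------------------------------------------------------------------------

def _trunc_norm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    if lo == -math.inf and hi == math.inf:
        return mean + sd * rng.standard_normal()
    a = (lo - mean) / sd if lo > -math.inf else -math.inf
    b = (hi - mean) / sd if hi < math.inf else math.inf
    Fa = ndtr(a) if a > -math.inf else 0.0
    Fb = ndtr(b) if b < math.inf else 1.0
    if Fb - Fa < 1e-300:
        # conditional mass numerically zero inside support: clamp to nearer edge
        return min(max(mean, lo), hi)
    u = Fa + rng.random() * (Fb - Fa)
    z = ndtri(min(max(u, 1e-300), 1.0 - 1e-16))
    return float(min(max(mean + sd * z, lo), hi))


# transform helpers for random-walk kinds: x <-> z with log-Jacobian dx/dz
def _to_unconstrained(kind: str, x: float) -> float:
    if kind == "rw_log":
        return math.log(x)
    if kind == "rw_atanh":
        return math.atanh(x)
    return x


def _from_unconstrained(kind: str, z: float) -> tuple[float, float]:
    """Return (x, log|dx/dz|)."""
    if kind == "rw_log":
        return math.exp(z), z
    if kind == "rw_atanh":
        x = math.tanh(z)
        return x, math.log(max(1.0 - x * x, 1e-300))
    return z, 0.0


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def sample(
    model: ComposedModel,
    config: SamplerConfig,
    init: dict | None = None,
    record: list[str] | None = None,
) -> PosteriorDraws:
    """Run Metropolis-within-Gibbs and return post-warmup draws.

    Parameters
    ----------
    model : ComposedModel
        Assembled posterior log density with parameter supports.
    config : SamplerConfig
        Chains receive distinct deterministic substreams of ``config.seed``,
        so the same seed and config always reproduce the same draws.
    init : dict, optional
        Starting values overriding the parameter defaults.
    record : list of str, optional
        Subset of parameters to store (default: all).
    """
    names = model.param_names
    record = list(names) if record is None else record
    unknown = set(record) - set(names) - set(model.extra_state)
    if unknown:
        raise ValueError(f"cannot record unknown parameters {sorted(unknown)}")

    state0 = model.init_state(init)
    lp0 = model.logpost(state0)
    if not np.isfinite(lp0):
        raise ValueError(
            "posterior log density is not finite at the initial values; "
            "re-initialize inside the parameter supports"
        )

    out = {n: np.empty((config.chains, config.draws)) for n in record}
    accept_count: dict[str, float] = {p.name: 0.0 for p in model.params}
    prop_count: dict[str, float] = {p.name: 0.0 for p in model.params}

    root = np.random.SeedSequence(config.seed)
    chain_seeds = root.spawn(config.chains)

    for c in range(config.chains):
        rng = np.random.default_rng(chain_seeds[c])
        state = dict(state0)
        steps = {p.name: p.step for p in model.params}
        total = config.warmup + config.draws
        for it in range(total):
            adapting = it < config.warmup
            for p in model.params:
                if p.kind == "gaussian":
                    _gaussian_gibbs(model, p, state, rng, steps)
                else:
                    acc = _rw_update(model, p, state, rng, steps[p.name])
                    if adapting:
                        # Robbins-Monro adaptation toward target acceptance
                        gamma = config.adapt_rate / math.sqrt(it + 1.0)
                        steps[p.name] *= math.exp(gamma * (acc - config.target_accept))
                    else:
                        accept_count[p.name] += acc
                        prop_count[p.name] += 1.0
            for upd in model.custom_updates:
                upd(state, rng)
            if not adapting:
                d = it - config.warmup
                for n in record:
                    out[n][c, d] = state[n]
        lp = model.logpost(state)
        if not np.isfinite(lp):
            raise RuntimeError(f"chain {c}: log density became non-finite; state={state}")

    acceptance = {
        n: (accept_count[n] / prop_count[n]) for n in accept_count if prop_count[n] > 0
    }
    for n, a in acceptance.items():
        logger.info("acceptance rate %s: %.3f", n, a)
    _check_supports(model, out)
    return PosteriorDraws(out, config=config, model_meta=dict(model.meta), acceptance=acceptance)


def _gaussian_gibbs(
    model: ComposedModel,
    p: ParamSpec,
    state: dict,
    rng: np.random.Generator,
    steps: dict,
) -> None:
    """Exact Gibbs draw for a parameter with a Gaussian full conditional.

    The conditional log density is quadratic in the parameter, so three
    evaluations identify it exactly: curvature from the symmetric second
    difference, gradient from the central first difference.
    """
    x = state[p.name]
    h = max(abs(x) * 1e-4, 1e-3)
    f0 = model.cond_logpost(p.name, state)
    state[p.name] = x + h
    fp = model.cond_logpost(p.name, state)
    state[p.name] = x - h
    fm = model.cond_logpost(p.name, state)
    state[p.name] = x
    # probes may step outside a truncated-uniform prior; retry inward
    if not (np.isfinite(fp) and np.isfinite(fm) and np.isfinite(f0)):
        h = h * 0.25
        state[p.name] = x + h
        fp = model.cond_logpost(p.name, state)
        state[p.name] = x - h
        fm = model.cond_logpost(p.name, state)
        state[p.name] = x
        if not (np.isfinite(fp) and np.isfinite(fm)):
            _rw_update(model, p, state, rng, steps[p.name])
            return
    curv = (fp + fm - 2.0 * f0) / (h * h)
    if curv >= -1e-12:  # flat or ill-conditioned conditional: fall back
        _rw_update(model, p, state, rng, steps[p.name])
        return
    var = -1.0 / curv
    grad = (fp - fm) / (2.0 * h)
    mean = x + grad * var
    state[p.name] = _trunc_norm(rng, mean, math.sqrt(var), p.lower, p.upper)


def _rw_update(
    model: ComposedModel,
    p: ParamSpec,
    state: dict,
    rng: np.random.Generator,
    step: float,
) -> float:
    """One random-walk Metropolis step on the transformed scale; returns 0/1."""
    kind = p.kind if p.kind != "gaussian" else "rw"
    x = state[p.name]
    z = _to_unconstrained(kind, x)
    _, ljac0 = _from_unconstrained(kind, z)
    f0 = model.cond_logpost(p.name, state) + ljac0
    z1 = z + step * rng.standard_normal()
    x1, ljac1 = _from_unconstrained(kind, z1)
    if not (p.lower <= x1 <= p.upper):
        return 0.0
    state[p.name] = x1
    f1 = model.cond_logpost(p.name, state) + ljac1
    if not np.isfinite(f1) or math.log(rng.random() + 1e-300) >= f1 - f0:
        state[p.name] = x
        return 0.0
    return 1.0


def _check_supports(model: ComposedModel, out: dict[str, np.ndarray]) -> None:
    by_name = {p.name: p for p in model.params}
    for n, arr in out.items():
        p = by_name.get(n)
        if p is None:
            continue
        if arr.min() < p.lower - 1e-12 or arr.max() > p.upper + 1e-12:
            raise RuntimeError(f"draws of {n} left support [{p.lower}, {p.upper}]")


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------

def gelman_rubin(draws: PosteriorDraws) -> dict[str, float]:
    """Split-chain potential scale reduction factor (R-hat) per parameter.

    Each chain is split in half, giving 2*chains sequences; R-hat compares
    between- and within-sequence variance.  A single chain is handled by
    the same split (two half-chains).  Zero-variance parameters report 1.0
    with a degenerate-parameter warning.
    """
    out = {}
    for name, arr in draws.draws.items():
        chains = []
        for c in range(arr.shape[0]):
            half = arr.shape[1] // 2
            if half < 2:
                chains.append(arr[c])
                continue
            chains.append(arr[c, :half])
            chains.append(arr[c, half : 2 * half])
        mat = np.array(chains, dtype=float)
        m, n = mat.shape
        if np.ptp(mat) == 0.0:
            logger.warning("gelman_rubin: parameter %s is degenerate (zero variance)", name)
            out[name] = 1.0
            continue
        chain_means = mat.mean(axis=1)
        W = mat.var(axis=1, ddof=1).mean()
        B_over_n = chain_means.var(ddof=1)
        if W == 0.0:
            out[name] = math.inf
            continue
        var_plus = (n - 1) / n * W + B_over_n
        out[name] = float(math.sqrt(var_plus / W))
    return out


def effective_sample_size(draws: PosteriorDraws) -> dict[str, float]:
    """Crude ESS from lag-autocorrelations (Geyer initial positive sequence)."""
    out = {}
    for name, arr in draws.draws.items():
        x = arr.reshape(-1).astype(float)
        n = len(x)
        x = x - x.mean()
        denom = float(np.dot(x, x))
        if denom == 0.0:
            out[name] = float(n)
            continue
        rho_sum = 0.0
        for lag in range(1, min(n - 1, 200)):
            r = float(np.dot(x[:-lag], x[lag:])) / denom
            if r < 0.05:
                break
            rho_sum += r
        out[name] = float(n / (1.0 + 2.0 * rho_sum))
    return out


def summarize(draws: PosteriorDraws, level: float = 0.95) -> pd.DataFrame:
    """Posterior median and central credible interval per parameter.

    The interval endpoints are the empirical (1-level)/2 and 1-(1-level)/2
    percentiles (linear interpolation between order statistics); the point
    estimate is the posterior median.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    rows = []
    for name in draws.names():
        x = draws.stacked(name)
        lo, med, hi = np.percentile(x, [100 * alpha, 50.0, 100 * (1 - alpha)])
        rows.append({"parameter": name, "median": med, "lower": lo, "upper": hi})
    return pd.DataFrame(rows).set_index("parameter")


def prob_event(
    draws: PosteriorDraws, predicate: Callable[[dict], bool]
) -> tuple[float, float]:
    """Posterior probability of an event, with its Monte-Carlo standard error.

    ``predicate`` receives one draw as a dict of parameter values and
    returns a boolean.  The probability is the fraction of draws where it
    holds; the MCSE is the binomial standard error sqrt(p(1-p)/n) (a
    lower bound under autocorrelation).
    """
    names = draws.names()
    flat = {n: draws.stacked(n) for n in names}
    n = len(next(iter(flat.values())))
    hits = 0
    for i in range(n):
        if predicate({k: v[i] for k, v in flat.items()}):
            hits += 1
    p = hits / n
    return p, math.sqrt(max(p * (1.0 - p), 0.0) / n)


def prob_less_than(values: np.ndarray, threshold: float = 0.0) -> float:
    """Fraction of draws below a threshold (vectorized convenience)."""
    values = np.asarray(values)
    return float(np.mean(values < threshold))
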