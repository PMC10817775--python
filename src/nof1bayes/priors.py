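"""Prior distributions for model parameters.

Priors are deliberately simple: bounded uniforms tailored to the outcome
scale (the default for bounded patient-reported outcomes), flat-but-proper
normals with huge variance for unbounded mean-type parameters, and uniforms
on (-1, 1) for correlations and (0, upper) for standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class Prior:
    """A univariate prior: ``uniform(a, b)`` or ``normal(mean, var)``."""

    dist: str  # "uniform" | "normal"
    a: float
    b: float

    def logpdf(self, x: float) -> float:
        if self.dist == "uniform":
            if self.a <= x <= self.b:
                return -math.log(self.b - self.a)
            return -math.inf
        if self.dist == "normal":
            return -0.5 * ((x - self.a) ** 2 / self.b + math.log(2.0 * math.pi * self.b))
        raise ValueError(f"unknown prior distribution {self.dist!r}")

    @property
    def support(self) -> tuple[float, float]:
        if self.dist == "uniform":
            return (self.a, self.b)
        return (-math.inf, math.inf)

    def midpoint(self) -> float:
        """A reasonable initial value inside the support."""
        if self.dist == "uniform":
            return 0.5 * (self.a + self.b)
        return self.a


def uniform(a: float, b: float) -> Prior:
    return Prior("uniform", float(a), float(b))


def normal(mean: float, var: float) -> Prior:
    return Prior("normal", float(mean), float(var))


@dataclass
class PriorSpec:
    """Named priors for every model parameter, with a fallback default."""

    priors: dict[str, Prior] = field(default_factory=dict)
    default: Prior = field(default_factory=lambda: normal(0.0, 1e6))

    def __getitem__(self, name: str) -> Prior:
        if name in self.priors:
            return self.priors[name]
        # family lookup: "delta[2]" falls back to "delta"
        base = name.split("[")[0]
        return self.priors.get(base, self.default)

    def __setitem__(self, name: str, prior: Prior) -> None:
        self.priors[name] = prior

    def __contains__(self, name: str) -> bool:
        return name in self.priors or name.split("[")[0] in self.priors

    def to_dict(self) -> dict:
        return {
            name: {"dist": p.dist, "a": p.a, "b": p.b} for name, p in self.priors.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls({name: Prior(v["dist"], float(v["a"]), float(v["b"])) for name, v in d.items()})
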