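"""Prior distributions with unconstrained-space transforms for MCMC.

Each prior knows how to map between its natural (constrained) scale ``x`` and
an unconstrained sampling coordinate ``u``, and evaluates the log prior density
*in u-space* (i.e. including the transform Jacobian), so samplers can work in
an unbounded geometry.

Log-normal priors follow the convention used throughout this package: the
stated location is the median on the natural scale and the spread is a standard
deviation in log10 units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Uniform", "LogNormal10", "LogUniform10", "HalfNormal"]

_LN10 = np.log(10.0)


def _log_sigmoid(u: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -u)


def _sigmoid(u: np.ndarray) -> np.ndarray:
    return np.exp(_log_sigmoid(u))


@dataclass(frozen=True)
class Uniform:
    """Uniform(lo, hi); sampled through a logit transform."""

    lo: float
    hi: float

    def x_from_u(self, u):
        return self.lo + (self.hi - self.lo) * _sigmoid(np.asarray(u, float))

    def u_from_x(self, x):
        p = (np.asarray(x, float) - self.lo) / (self.hi - self.lo)
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return np.log(p) - np.log1p(-p)

    def logpdf_u(self, u):
        u = np.asarray(u, float)
        # log s(u) + log (1 - s(u)); the 1/(hi-lo) density cancels the width
        # factor of the Jacobian up to a constant dropped here
        return _log_sigmoid(u) + _log_sigmoid(-u)

    def sample_x(self, rng: np.random.Generator, size):
        return rng.uniform(self.lo, self.hi, size=size)

    @property
    def median(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class LogNormal10:
    """x > 0 with log10(x) ~ Normal(log10(median), sd10)."""

    median: float
    sd10: float

    def x_from_u(self, u):
        return np.exp(np.asarray(u, float))

    def u_from_x(self, x):
        return np.log(np.asarray(x, float))

    def logpdf_u(self, u):
        # u = ln x is exactly Normal(ln median, sd10 * ln 10)
        mu = np.log(self.median)
        sd = self.sd10 * _LN10
        z = (np.asarray(u, float) - mu) / sd
        return -0.5 * z * z - np.log(sd)

    def sample_x(self, rng: np.random.Generator, size):
        return self.median * 10.0 ** rng.normal(0.0, self.sd10, size=size)


@dataclass(frozen=True)
class LogUniform10:
    """log10(x) ~ Uniform(log10(lo), log10(hi)); logit-transformed."""

    lo: float
    hi: float

    def _box(self) -> Uniform:
        return Uniform(np.log10(self.lo), np.log10(self.hi))

    def x_from_u(self, u):
        return 10.0 ** self._box().x_from_u(u)

    def u_from_x(self, x):
        return self._box().u_from_x(np.log10(np.asarray(x, float)))

    def logpdf_u(self, u):
        return self._box().logpdf_u(u)

    def sample_x(self, rng: np.random.Generator, size):
        return 10.0 ** self._box().sample_x(rng, size)

    @property
    def median(self) -> float:
        return float(np.sqrt(self.lo * self.hi))


@dataclass(frozen=True)
class HalfNormal:
    """x > 0 with density prop. to exp(-x^2 / (2 scale^2)); log-transformed."""

    scale: float

    def x_from_u(self, u):
        return np.exp(np.asarray(u, float))

    def u_from_x(self, x):
        return np.log(np.asarray(x, float))

    def logpdf_u(self, u):
        u = np.asarray(u, float)
        with np.errstate(over="ignore"):
            x = np.exp(u)
            return -0.5 * (x / self.scale) ** 2 + u - np.log(self.scale)

    def sample_x(self, rng: np.random.Generator, size):
        return np.abs(rng.normal(0.0, self.scale, size=size))

    @property
    def median(self) -> float:
        return 0.6744897501960817 * self.scale
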