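"""Ensemble-MCMC engine shared by every fitting mode.

Models are declared as an ordered set of named parameter blocks, each carrying
a prior from :mod:`growthdeath.priors`. Sampling runs in the unconstrained
space with an affine-invariant ensemble sampler (emcee), initialized from a
numerically located posterior mode. Effective sample sizes come from the
ensemble's integrated autocorrelation time; the Geweke score compares the
first and second half of a run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import emcee
import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["ParamBlock", "ParamSet", "PosteriorSamples", "run_fit", "ess_1d", "geweke_z"]


@dataclass(frozen=True)
class ParamBlock:
    """A named group of parameters sharing one prior family.

    ``labels`` names the individual entries (defaults to the block name for
    size-1 blocks, ``name[i]`` otherwise).
    """

    name: str
    prior: object
    size: int = 1
    labels: tuple[str, ...] | None = None

    def expanded_labels(self) -> list[str]:
        if self.labels is not None:
            if len(self.labels) != self.size:
                raise ValueError(f"block {self.name}: {self.size} entries but "
                                 f"{len(self.labels)} labels")
            return list(self.labels)
        if self.size == 1:
            return [self.name]
        return [f"{self.name}[{i}]" for i in range(self.size)]


class ParamSet:
    """Ordered parameter blocks with packing helpers."""

    def __init__(self, blocks: Sequence[ParamBlock]):
        self.blocks = list(blocks)
        self.slices: dict[str, slice] = {}
        start = 0
        for b in self.blocks:
            self.slices[b.name] = slice(start, start + b.size)
            start += b.size
        self.ndim = start
        self.labels: list[str] = []
        for b in self.blocks:
            self.labels.extend(b.expanded_labels())

    def unpack(self, u: np.ndarray) -> dict[str, np.ndarray]:
        """Constrained-scale values, keyed by block name; u has shape (K, D)."""
        return {
            b.name: b.prior.x_from_u(u[..., self.slices[b.name]])
            for b in self.blocks
        }

    def log_prior_u(self, u: np.ndarray) -> np.ndarray:
        lp = np.zeros(u.shape[:-1])
        for b in self.blocks:
            lp = lp + b.prior.logpdf_u(u[..., self.slices[b.name]]).sum(axis=-1)
        return lp

    def u_from_values(self, values: Mapping[str, np.ndarray]) -> np.ndarray:
        u = np.empty(self.ndim)
        for b in self.blocks:
            u[self.slices[b.name]] = np.atleast_1d(b.prior.u_from_x(values[b.name]))
        return u

    def sample_u(self, rng: np.random.Generator, n: int) -> np.ndarray:
        u = np.empty((n, self.ndim))
        for b in self.blocks:
            x = b.prior.sample_x(rng, (n, b.size))
            u[:, self.slices[b.name]] = b.prior.u_from_x(x)
        return u


def ess_1d(chain: np.ndarray) -> float:
    """Effective sample size of one parameter.

    ``chain`` has shape (n_steps, n_walkers) (a single flat series is treated
    as one walker). Uses the ensemble-averaged integrated autocorrelation
    time; an i.i.d. series returns roughly its length.
    """
    c = np.asarray(chain, float)
    if c.ndim == 1:
        c = c[:, None]
    n = c.size
    if np.ptp(c) == 0:
        return 0.0
    logger = logging.getLogger("emcee.autocorr")
    level = logger.level
    try:
        logger.setLevel(logging.ERROR)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tau = float(emcee.autocorr.integrated_time(c, quiet=True)[0])
    except Exception:
        return 0.0
    finally:
        logger.setLevel(level)
    tau = max(tau, 1.0)
    return n / tau


def geweke_z(chain: np.ndarray) -> float:
    """First-half vs second-half mean comparison for one parameter.

    z = (m1 - m2) / sqrt(var1/ess1 + var2/ess2); |z| > 2 flags nonstationarity.
    """
    c = np.asarray(chain, float)
    if c.ndim == 1:
        c = c[:, None]
    half = c.shape[0] // 2
    a, b = c[:half], c[half:]
    ess_a, ess_b = max(ess_1d(a), 1.0), max(ess_1d(b), 1.0)
    se = np.sqrt(a.var() / ess_a + b.var() / ess_b)
    if se == 0:
        return 0.0
    return float((a.mean() - b.mean()) / se)


@dataclass
class PosteriorSamples:
    """Posterior draws on the natural parameter scale.

    ``chain`` has shape (n_steps, n_walkers, n_params); ``labels`` names the
    last axis. ``meta`` records the seed and fitting configuration; the
    ``converged`` flag is False when the effective-sample-size gate failed
    even after the tuning retry.
    """

    labels: list[str]
    chain: np.ndarray
    converged: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n_draws(self) -> int:
        return self.chain.shape[0] * self.chain.shape[1]

    def draws(self, label: str) -> np.ndarray:
        """All draws of one parameter, flattened across walkers."""
        return self.chain[:, :, self._index[label]].reshape(-1)

    def walker_chain(self, label: str) -> np.ndarray:
        return self.chain[:, :, self._index[label]]

    def mean(self, label: str) -> float:
        return float(self.draws(label).mean())

    def interval(self, label: str, level: float = 0.95) -> tuple[float, float]:
        """Equal-tailed posterior quantile interval."""
        if not (0.0 < level < 1.0):
            raise ValueError("level must lie in (0, 1)")
        a = (1.0 - level) / 2.0
        d = self.draws(label)
        return float(np.quantile(d, a)), float(np.quantile(d, 1.0 - a))

    def ess(self, label: str) -> float:
        return ess_1d(self.walker_chain(label))

    def geweke(self, label: str) -> float:
        return geweke_z(self.walker_chain(label))

    def summary(self) -> pd.DataFrame:
        """Per-parameter posterior summary table."""
        rows = []
        for lab in self.labels:
            d = self.draws(lab)
            rows.append(
                dict(
                    parameter=lab,
                    mean=d.mean(),
                    sd=d.std(),
                    q05=np.quantile(d, 0.05),
                    q50=np.quantile(d, 0.50),
                    q95=np.quantile(d, 0.95),
                    ess=self.ess(lab),
                    geweke_z=self.geweke(lab),
                )
            )
        return pd.DataFrame(rows)


def _find_mode(
    params: ParamSet,
    log_likelihood_u: Callable[[np.ndarray], np.ndarray],
    init_u: np.ndarray | None = None,
) -> np.ndarray:
    """Approximate posterior mode in u-space by sequential simplex polishing."""

    def neg_logpost(u_flat: np.ndarray) -> float:
        u = u_flat[None, :]
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            val = params.log_prior_u(u)[0] + float(log_likelihood_u(u)[0])
        if not np.isfinite(val):
            return 1e30
        return -val

    if init_u is None:
        init_u = params.u_from_values(
            {b.name: np.full(b.size, _prior_center(b.prior))
             for b in params.blocks}
        )
    best = np.asarray(init_u, dtype=float)
    for _ in range(2):  # Nelder-Mead benefits from a simplex restart
        res = optimize.minimize(
            neg_logpost, best, method="Nelder-Mead",
            options=dict(maxiter=400 * params.ndim, maxfev=400 * params.ndim,
                         xatol=1e-6, fatol=1e-6, adaptive=True),
        )
        best = res.x
    return best


def _prior_center(prior) -> float:
    return float(getattr(prior, "median"))


def run_fit(
    params: ParamSet,
    log_likelihood: Callable[[dict[str, np.ndarray]], np.ndarray],
    seed: int,
    walkers: int = 64,
    tune: int = 800,
    draws: int = 400,
    min_ess: float = 200.0,
    retry: bool = True,
    gate_labels: Sequence[str] | None = None,
    init_values: Mapping[str, np.ndarray] | None = None,
    init_style: str = "map",
    meta: dict | None = None,
) -> PosteriorSamples:
    """Sample the posterior of a declared model.

    ``log_likelihood`` receives a dict of constrained-scale arrays with leading
    walker axis K and returns shape (K,). ``init_values`` (constrained scale,
    keyed by block name) seeds the mode search; crude moment estimates are
    enough. On failing the ESS gate the sampler retries once with doubled
    tuning; a still-failing run is returned with ``converged=False`` rather
    than silently accepted.
    """
    rng = np.random.default_rng(seed)

    def loglik_u(u: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return log_likelihood(params.unpack(u))

    def logpost(u: np.ndarray) -> np.ndarray:
        lp = params.log_prior_u(u)
        out = np.full(u.shape[0], -np.inf)
        ok = np.isfinite(lp)
        if np.any(ok):
            ll = loglik_u(u[ok])
            out[ok] = lp[ok] + np.where(np.isfinite(ll), ll, -np.inf)
        out[~np.isfinite(out)] = -np.inf
        return out

    init_u = params.u_from_values(init_values) if init_values else None
    u_map = _find_mode(params, loglik_u, init_u)

    # differential-evolution moves traverse the ridge-like posteriors of this
    # model family far better than the default stretch move
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    attempt_tune = tune
    for attempt in range(2 if retry else 1):
        if init_style == "prior":
            p0 = params.sample_u(rng, walkers)
            # keep a quarter of the walkers near the mode so the ensemble
            # bridges between prior mass and the high-likelihood region
            p0[: walkers // 4] = u_map[None, :] + 0.05 * rng.standard_normal(
                (walkers // 4, params.ndim))
        else:
            p0 = u_map[None, :] + 0.05 * rng.standard_normal(
                (walkers, params.ndim))
        sampler = emcee.EnsembleSampler(
            walkers, params.ndim, logpost, vectorize=True, moves=moves
        )
        state = sampler.run_mcmc(p0, attempt_tune, progress=False,
                                 skip_initial_state_check=True)
        sampler.reset()
        sampler.run_mcmc(state, draws, progress=False,
                         skip_initial_state_check=True)
        u_chain = sampler.get_chain()  # (draws, walkers, D)
        x_chain = np.empty_like(u_chain)
        for b in params.blocks:
            sl = params.slices[b.name]
            x_chain[:, :, sl] = b.prior.x_from_u(u_chain[:, :, sl])
        post = PosteriorSamples(
            labels=list(params.labels),
            chain=x_chain,
            meta=dict(meta or {}, seed=seed, walkers=walkers,
                      tune=attempt_tune, draws=draws,
                      accept_frac=float(sampler.acceptance_fraction.mean())),
        )
        check = list(gate_labels) if gate_labels is not None else post.labels
        ess_vals = np.array([post.ess(lab) for lab in check])
        post.meta["min_ess"] = float(ess_vals.min()) if ess_vals.size else 0.0
        if post.meta["min_ess"] >= min_ess:
            post.converged = True
            return post
        attempt_tune *= 2  # retry policy: double tuning once, then flag
    post.converged = False
    return post
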