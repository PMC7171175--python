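"""Four-compartment cell growth/death kinetics.

The population is tracked per starting cell in four states: live cells ``L``,
early-apoptotic cells ``E``, dead cells via apoptosis ``Da``, and dead cells via
a non-apoptotic route ``Dn``. Live cells divide at rate ``div`` (R_g) and die at
rate ``deathRate`` (R_d); a fraction ``apopFrac`` (f) of dying cells enters early
apoptosis and proceeds to late apoptosis at rate ``d`` (tau), while the rest die
directly by a non-apoptotic process:

    dL/dt  = (R_g - R_d) L
    dE/dt  = R_d f L - tau E
    dDa/dt = tau E
    dDn/dt = R_d (1 - f) L

Death moves cells between compartments and never removes them, so the total
population obeys d(total)/dt = R_g L. With gamma = R_g - R_d and
phi(x) = (e^x - 1)/x the system has the exact solution (from L(0)=1,
E=Da=Dn=0):

    L(t)      = exp(gamma t)
    deaths(t) = R_d t phi(gamma t)            (cumulative dead cells)
    E(t)      = R_d f t exp(-tau t) phi((gamma + tau) t)
    Da(t)     = f deaths(t) - E(t)
    Dn(t)     = (1 - f) deaths(t)

All rates are per hour; times are hours. Absolute scale (percent image area)
lives entirely in :class:`ObservationModel` conversion factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RateParameters",
    "StateVector",
    "Trajectory",
    "ObservationModel",
    "ode_rhs",
    "analytic_state",
    "simulate_trajectory",
    "cumulative_events",
    "viability_tradeoff",
    "observables",
    "state_arrays",
]


@dataclass(frozen=True)
class RateParameters:
    """Kinetic rates governing one drug condition.

    Parameters
    ----------
    div
        Division rate R_g (1/h), >= 0.
    death_rate
        Death rate R_d (1/h), >= 0.
    apop_frac
        Fraction f of dying cells entering apoptosis, in [0, 1].
    transition_rate
        Early -> late apoptosis transition rate tau (1/h), > 0. Conventionally
        written ``d`` in reports.
    """

    div: float
    death_rate: float
    apop_frac: float
    transition_rate: float

    def __post_init__(self) -> None:
        if not (self.div >= 0.0):
            raise ValueError(f"div must be >= 0, got {self.div}")
        if not (self.death_rate >= 0.0):
            raise ValueError(f"death_rate must be >= 0, got {self.death_rate}")
        if not (0.0 <= self.apop_frac <= 1.0):
            raise ValueError(f"apop_frac must lie in [0, 1], got {self.apop_frac}")
        if not (self.transition_rate > 0.0):
            raise ValueError(
                f"transition_rate must be > 0, got {self.transition_rate}"
            )

    @property
    def gamma(self) -> float:
        """Net growth rate R_g - R_d (1/h)."""
        return self.div - self.death_rate


@dataclass(frozen=True)
class StateVector:
    """Cells per starting cell in each compartment at one time point."""

    L: float
    E: float
    Da: float
    Dn: float

    def __post_init__(self) -> None:
        for name in ("L", "E", "Da", "Dn"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"state component {name} must be >= 0")

    @property
    def total(self) -> float:
        return self.L + self.E + self.Da + self.Dn

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.E, self.Da, self.Dn], dtype=float)


@dataclass(frozen=True)
class Trajectory:
    """States along a strictly increasing time grid (hours)."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 4), columns L, E, Da, Dn

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "states", np.asarray(self.states, dtype=float))
        if self.times.ndim != 1 or self.states.shape != (self.times.size, 4):
            raise ValueError("states must have shape (len(times), 4)")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        """Tidy export (columns time_h, L, E, Da, Dn) for debugging."""
        return pd.DataFrame(
            {
                "time_h": self.times,
                "L": self.states[:, 0],
                "E": self.states[:, 1],
                "Da": self.states[:, 2],
                "Dn": self.states[:, 3],
            }
        )


@dataclass(frozen=True)
class ObservationModel:
    """Mapping from compartments to the three percent-area channels.

    Confluence (phase) counts cells in every state; Annexin V marks early plus
    late apoptotic cells; YOYO-3 marks every cell that has lost membrane
    integrity (late apoptotic and non-apoptotic dead). Each channel has a
    conversion factor (percent area per starting-cell unit), a background
    offset (percent area) and an additive Gaussian noise scale.
    """

    conv_phase: float = 5.0
    conv_annexin: float = 2.0
    conv_yoyo: float = 2.0
    bg_phase: float = 0.1
    bg_annexin: float = 0.1
    bg_yoyo: float = 0.1
    sd_phase: float = 0.5
    sd_annexin: float = 0.2
    sd_yoyo: float = 0.2

    def __post_init__(self) -> None:
        if min(self.conv_phase, self.conv_annexin, self.conv_yoyo) <= 0:
            raise ValueError("conversion factors must be > 0")
        if min(self.bg_phase, self.bg_annexin, self.bg_yoyo) < 0:
            raise ValueError("backgrounds must be >= 0")
        if min(self.sd_phase, self.sd_annexin, self.sd_yoyo) <= 0:
            raise ValueError("noise scales must be > 0")

    @property
    def conversions(self) -> np.ndarray:
        return np.array([self.conv_phase, self.conv_annexin, self.conv_yoyo])

    @property
    def backgrounds(self) -> np.ndarray:
        return np.array([self.bg_phase, self.bg_annexin, self.bg_yoyo])

    @property
    def noise_sd(self) -> np.ndarray:
        return np.array([self.sd_phase, self.sd_annexin, self.sd_yoyo])


def _phi(x: np.ndarray) -> np.ndarray:
    """(e^x - 1)/x, continuous through x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-9
    out[small] = 1.0 + x[small] / 2.0 + x[small] ** 2 / 6.0
    xs = x[~small]
    out[~small] = np.expm1(xs) / xs
    return out


def state_arrays(
    div: np.ndarray,
    death_rate: np.ndarray,
    apop_frac: np.ndarray,
    transition_rate: np.ndarray,
    times: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized closed-form states.

    Rate arrays broadcast against each other (shape ``S``); ``times`` has shape
    ``(T,)``. Returns ``(L, E, Da, Dn)`` each of shape ``S + (T,)``.
    """
    div, death_rate, apop_frac, transition_rate = np.broadcast_arrays(
        np.asarray(div, float),
        np.asarray(death_rate, float),
        np.asarray(apop_frac, float),
        np.asarray(transition_rate, float),
    )
    t = np.asarray(times, dtype=float)
    g = (div - death_rate)[..., None]
    rd = death_rate[..., None]
    f = apop_frac[..., None]
    tau = transition_rate[..., None]

    with np.errstate(over="ignore", invalid="ignore"):
        L = np.exp(g * t)
        deaths = rd * t * _phi(g * t)
        E = rd * f * t * np.exp(-tau * t) * _phi((g + tau) * t)
        Da = f * deaths - E
        Dn = (1.0 - f) * deaths
    # the cascade solution is nonnegative analytically; clip roundoff only
    Da = np.where(Da < 0, 0.0, Da)
    return L, E, Da, Dn


def ode_rhs(state: StateVector, params: RateParameters) -> np.ndarray:
    """Time derivative [dL, dE, dDa, dDn] of the compartment model."""
    L, E = state.L, state.E
    return np.array(
        [
            params.gamma * L,
            params.death_rate * params.apop_frac * L - params.transition_rate * E,
            params.transition_rate * E,
            params.death_rate * (1.0 - params.apop_frac) * L,
        ]
    )


def analytic_state(params: RateParameters, t: float) -> StateVector:
    """Exact state at time ``t`` (hours) from the initial state (1, 0, 0, 0)."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    L, E, Da, Dn = state_arrays(
        params.div,
        params.death_rate,
        params.apop_frac,
        params.transition_rate,
        np.array([t]),
    )
    return StateVector(float(L[0]), float(E[0]), float(Da[0]), float(Dn[0]))


def simulate_trajectory(params: RateParameters, times: Sequence[float]) -> Trajectory:
    """Closed-form trajectory over a nonnegative, increasing time grid."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a nonempty 1-D sequence")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    L, E, Da, Dn = state_arrays(
        params.div, params.death_rate, params.apop_frac, params.transition_rate, t
    )
    return Trajectory(times=t, states=np.stack([L, E, Da, Dn], axis=-1))


def cumulative_events(params: RateParameters, t: float) -> tuple[float, float]:
    """Cumulative divisions and deaths per starting cell up to time ``t``.

    These are the integrals of R_g L and R_d L: ``R t phi(gamma t)`` for each
    rate, with the gamma -> 0 limit ``R t`` handled by the series in ``phi``.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    gt = np.array([params.gamma * t])
    growth_integral = float(t * _phi(gt)[0])
    return params.div * growth_integral, params.death_rate * growth_integral


def viability_tradeoff(
    target_viability: float,
    control_growth: float,
    t: float,
    split_grid: Sequence[float],
    apop_frac: float = 0.7,
    transition_rate: float = 0.04,
) -> pd.DataFrame:
    """Divisions/deaths trade-off at a fixed viability.

    For each ``split`` in [0, 1] (0 = pure growth inhibition, 1 = pure death
    induction) solve for rates reproducing ``L(t)/L_control(t) =
    target_viability``: the total rate effect is ``delta = -ln(V)/t``,
    apportioned as ``death_rate = split * delta`` and ``div = g0 - (1 - split) *
    delta``. Returns a table of (split, div, death_rate, divisions, deaths,
    feasible); rows where the pure-growth share would force div < 0 are marked
    infeasible.
    """
    if not (0.0 < target_viability < 1.0):
        raise ValueError("target_viability must lie strictly in (0, 1)")
    delta = -np.log(target_viability) / t
    rows = []
    for split in split_grid:
        if not (0.0 <= split <= 1.0):
            raise ValueError(f"split must lie in [0, 1], got {split}")
        rd = split * delta
        rg = control_growth - (1.0 - split) * delta
        if rg < 0:
            rows.append((split, np.nan, rd, np.nan, np.nan, False))
            continue
        params = RateParameters(rg, rd, apop_frac, transition_rate)
        divisions, deaths = cumulative_events(params, t)
        rows.append((split, rg, rd, divisions, deaths, True))
    return pd.DataFrame(
        rows, columns=["split", "div", "death_rate", "divisions", "deaths", "feasible"]
    )


def observables(traj: Trajectory, obs: ObservationModel) -> pd.DataFrame:
    """Noiseless percent-area channels along a trajectory.

    phase = c_P (L+E+Da+Dn) + b_P;  annexin = c_A (E+Da) + b_A;
    yoyo = c_Y (Da+Dn) + b_Y.
    """
    L, E, Da, Dn = traj.states.T
    return pd.DataFrame(
        {
            "time_h": traj.times,
            "phase_pct": obs.conv_phase * (L + E + Da + Dn) + obs.bg_phase,
            "annexin_pct": obs.conv_annexin * (E + Da) + obs.bg_annexin,
            "yoyo_pct": obs.conv_yoyo * (Da + Dn) + obs.bg_yoyo,
        }
    )
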