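"""Hill dose-response coupling of compound concentration to growth/death rates.

A compound is described by one potency (EC50 == IC50, shared between the two
phenotypes), one Hill slope, and two separate maximal effects: a fractional
maximal growth inhibition in [0, 1] and a maximal death rate (1/h) reached at
saturating drug. Cells undergo no death in the absence of drug.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .kinetics import RateParameters

__all__ = ["HillPhenotypeCurve", "hill_fraction", "rates_at_dose", "viability_at_dose"]


def hill_fraction(conc, ec50: float, hill_slope: float):
    """Fractional Hill occupancy conc^h / (conc^h + ec50^h).

    Zero at conc = 0, 1/2 at conc = ec50, -> 1 as conc -> inf; strictly
    increasing. Vectorized over ``conc``.
    """
    if ec50 <= 0 or hill_slope <= 0:
        raise ValueError("ec50 and hill_slope must be > 0")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    # work on log-concentration for numerical stability at extreme doses
    with np.errstate(divide="ignore"):
        logr = hill_slope * (np.log(c) - np.log(ec50))
    frac = np.where(c == 0, 0.0, 1.0 / (1.0 + np.exp(-logr)))
    if np.isscalar(conc) or np.ndim(conc) == 0:
        return float(frac)
    return frac


@dataclass(frozen=True)
class HillPhenotypeCurve:
    """Dose-response of one compound on growth and death rates.

    Fields
    ------
    ec50 : concentration at half-maximal effect (dose units of the assay).
    hill_slope : Hill coefficient (dimensionless), shared by both phenotypes.
    control_growth : division rate with no drug (1/h).
    emax_growth_inhib : maximal fractional growth inhibition in [0, 1]
        (1.0 = complete growth arrest at saturating drug).
    emax_death_rate : maximal death rate at saturating drug (1/h).
    """

    ec50: float
    hill_slope: float
    control_growth: float
    emax_growth_inhib: float
    emax_death_rate: float

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.hill_slope <= 0:
            raise ValueError("hill_slope must be > 0")
        if self.control_growth < 0:
            raise ValueError("control_growth must be >= 0")
        if not (0.0 <= self.emax_growth_inhib <= 1.0):
            raise ValueError("emax_growth_inhib must lie in [0, 1]")
        if self.emax_death_rate < 0:
            raise ValueError("emax_death_rate must be >= 0")

    def growth_inhibition(self, conc):
        """Fractional growth inhibition I(conc) in [0, emax_growth_inhib]."""
        return self.emax_growth_inhib * hill_fraction(conc, self.ec50, self.hill_slope)

    def death_rate(self, conc):
        """Death rate (1/h) at dose ``conc``; zero without drug."""
        return self.emax_death_rate * hill_fraction(conc, self.ec50, self.hill_slope)

    def to_dict(self) -> dict:
        """Flat key-value serialization of the curve parameters."""
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HillPhenotypeCurve":
        return cls(**{k: float(d[k]) for k in (
            "ec50", "hill_slope", "control_growth",
            "emax_growth_inhib", "emax_death_rate")})


def rates_at_dose(
    curve: HillPhenotypeCurve,
    conc: float,
    apop_frac: float,
    transition_rate: float,
) -> RateParameters:
    """Kinetic rates implied by a curve at one dose.

    div = control_growth (1 - emax_growth_inhib h(conc));
    death_rate = emax_death_rate h(conc).
    """
    h = hill_fraction(conc, curve.ec50, curve.hill_slope)
    return RateParameters(
        div=curve.control_growth * (1.0 - curve.emax_growth_inhib * h),
        death_rate=curve.emax_death_rate * h,
        apop_frac=apop_frac,
        transition_rate=transition_rate,
    )


def viability_at_dose(curve: HillPhenotypeCurve, conc, t: float):
    """Live-cell viability L(t; conc)/L(t; 0) = exp((gamma(c) - gamma(0)) t)."""
    if t <= 0:
        raise ValueError("t must be > 0")
    h = np.asarray(hill_fraction(conc, curve.ec50, curve.hill_slope))
    gamma_drop = (
        curve.control_growth * curve.emax_growth_inhib + curve.emax_death_rate
    ) * h
    v = np.exp(-gamma_drop * t)
    if np.ndim(conc) == 0:
        return float(v)
    return v
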