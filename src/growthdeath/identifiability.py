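"""Viability-only dose-response fitting and its growth/death confounding.

Fitting a growth+death Hill model to end-point viability alone leaves the
split between growth inhibition and death induction unidentified: any
parameter pair with the same net growth rate gamma(conc) produces the same
live-cell viability exp((gamma(c) - gamma(0)) t). This module fits that model
anyway (as one would to a typical dose-viability table) and quantifies the
resulting uncertainty in the underlying rates.

Model: growth rate declines from the drug-free rate ``g0`` (fixed from a
control measurement) toward a fitted minimum, death rises from zero toward a
fitted maximum, both along one shared Hill curve; residuals are Gaussian.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mcmc import ParamBlock, ParamSet, PosteriorSamples, run_fit
from .priors import HalfNormal, LogNormal10, LogUniform10, Uniform

__all__ = [
    "VIABILITY_COLUMNS",
    "validate_viability_assay",
    "fit_viability_only",
    "rate_intervals",
    "effect_correlation",
]

VIABILITY_COLUMNS = ["conc", "replicate", "viability"]


def validate_viability_assay(assay: pd.DataFrame) -> pd.DataFrame:
    """Check the (conc, replicate, viability) schema; returns a copy."""
    missing = [c for c in VIABILITY_COLUMNS if c not in assay.columns]
    if missing:
        raise ValueError(f"viability assay is missing columns: {missing}")
    df = assay.copy()
    for col in ("conc", "viability"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
        if bad:
            raise ValueError(f"column {col!r}: non-numeric values at rows {bad[:10]}")
        df[col] = pd.to_numeric(df[col])
    if (df["viability"] <= 0).any():
        raise ValueError("viability must be > 0 (relative to untreated control)")
    if df["conc"].nunique() < 2:
        raise ValueError("assay needs dose variation to fit a dose-response")
    return df


def fit_viability_only(
    assay: pd.DataFrame,
    t: float = 72.0,
    g0: float = 0.0315,
    seed: int = 0,
    walkers: int = 48,
    tune: int = 800,
    draws: int = 600,
    min_ess: float = 200.0,
) -> PosteriorSamples:
    """Fit the growth/death Hill model to viability measurements only.

    The drug-free growth rate ``g0`` (1/h) is fixed (measured experimentally)
    and death in the absence of drug is fixed at zero. Priors: minimum growth
    rate uniform on (0, g0); maximal death rate log-normal median 0.01 1/h,
    sd 2.0 log10; Hill slope log-normal median 1, sd 1 log10; EC50
    log-uniform over the assayed dose range padded by a decade each side;
    residual sd half-normal(0.1).
    """
    df = validate_viability_assay(assay)
    conc = df["conc"].to_numpy(dtype=float)
    v_obs = df["viability"].to_numpy(dtype=float)
    pos = conc[conc > 0]
    pset = ParamSet([
        ParamBlock("ec50", LogUniform10(pos.min() / 10.0, pos.max() * 10.0)),
        ParamBlock("hill_slope", LogNormal10(1.0, 1.0)),
        ParamBlock("growth_min", Uniform(0.0, g0)),
        ParamBlock("death_max", LogNormal10(0.01, 2.0)),
        ParamBlock("sigma", HalfNormal(0.1)),
    ])

    logc = np.log(np.where(conc > 0, conc, 1.0))

    def loglik(x: dict[str, np.ndarray]) -> np.ndarray:
        ec50 = x["ec50"][:, 0]
        slope = x["hill_slope"][:, 0]
        h = np.where(
            conc[None, :] > 0,
            1.0 / (1.0 + np.exp(-slope[:, None] *
                                (logc[None, :] - np.log(ec50)[:, None]))),
            0.0,
        )
        total_effect = (g0 - x["growth_min"][:, 0]) + x["death_max"][:, 0]
        v_pred = np.exp(-total_effect[:, None] * h * t)
        sd = x["sigma"][:, 0]
        z2 = np.sum(((v_obs[None, :] - v_pred) / sd[:, None]) ** 2, axis=1)
        n = v_obs.size
        return -0.5 * z2 - n * np.log(sd) - 0.5 * n * np.log(2 * np.pi)

    # seed the mode search: EC50 near the half-effect dose, effect size from
    # the deepest observed viability
    means = df.groupby("conc")["viability"].mean()
    ec50_init = float(means.index[(means - 0.5).abs().argmin()]) or float(
        np.exp(np.mean(np.log(pos))))
    total_effect = max(-np.log(max(means.min(), 1e-3)) / t, 1e-4)
    init = {
        "ec50": np.array([max(ec50_init, pos.min())]),
        "hill_slope": np.array([1.0]),
        "growth_min": np.array([g0 * 0.5]),
        "death_max": np.array([max(total_effect - 0.5 * g0, 1e-4)]),
        "sigma": np.array([0.03]),
    }
    post = run_fit(
        pset, loglik, seed=seed, walkers=walkers, tune=tune, draws=draws,
        min_ess=min_ess, init_values=init,
        meta={"mode": "viability", "g0": g0, "t": t,
              "max_dose": float(conc.max())},
    )
    return post


def _rate_draws(post: PosteriorSamples, conc: float):
    g0 = post.meta["g0"]
    if conc > 0:
        ec50 = post.draws("ec50")
        slope = post.draws("hill_slope")
        h = 1.0 / (1.0 + np.exp(-slope * (np.log(conc) - np.log(ec50))))
    else:
        h = np.zeros(post.n_draws)
    growth = g0 - (g0 - post.draws("growth_min")) * h
    death = post.draws("death_max") * h
    return growth, death


def rate_intervals(
    post: PosteriorSamples, conc: float, level: float = 0.90, per_day: bool = False
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Equal-tailed credible intervals of the implied rates at one dose.

    Returns ``((growth_lo, growth_hi), (death_lo, death_hi))`` in 1/h, or
    1/day with ``per_day=True`` (a reporting conversion only).
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    growth, death = _rate_draws(post, conc)
    a = (1.0 - level) / 2.0
    scale = 24.0 if per_day else 1.0
    gi = tuple(scale * np.quantile(growth, [a, 1 - a]))
    di = tuple(scale * np.quantile(death, [a, 1 - a]))
    return gi, di


def effect_correlation(post: PosteriorSamples, conc: float | None = None) -> float:
    """Correlation of the implied growth and death rates at a reference dose.

    Defaults to the assay's maximum dose. On viability-only posteriors the
    rates co-vary strongly along the confounding ridge (only their difference
    is constrained by live-cell data), so |r| is large; a three-channel fit
    breaks the ridge. Raises on degenerate (constant) marginals.
    """
    if conc is None:
        conc = post.meta["max_dose"]
    growth, death = _rate_draws(post, conc)
    if growth.std() == 0 or death.std() == 0:
        raise ValueError("correlation undefined for constant marginals")
    return float(np.corrcoef(growth, death)[0, 1])
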