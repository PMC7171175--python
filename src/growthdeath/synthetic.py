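"""Seeded synthetic experiments with the generative structure the fits assume.

Emulates triplicate IncuCyte-style wells sampled every 3 h over 72 h: channels
are the noiseless compartment observables plus additive Gaussian noise, doses
follow Hill dose-response truths, and combination grids are built from the
additive-rate null (optionally perturbed by a death-synergy factor). Every
generator is deterministic given the TruthSpec seed, and the truth is
available alongside the table for recovery tests.

Named fixtures sketch archetypal single-agent phenotypes (growth-dominant,
death-dominant, growth-only, death-only, mixed). Their parameter values are
fixture choices calibrated to realistic magnitudes, not measured values for
the eponymous compounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dose_response import (
    HillPhenotypeCurve,
    hill_fraction,
    rates_at_dose,
    viability_at_dose,
)
from .interaction import DoseGrid, combo_rates
from .kinetics import (
    ObservationModel,
    RateParameters,
    observables,
    simulate_trajectory,
)
from .inference import TIDY_COLUMNS

__all__ = [
    "TruthSpec",
    "FIXTURES",
    "fixture_truth",
    "prior_central_truth",
    "generate_recovery_experiment",
    "generate_single_agent",
    "generate_viability_assay",
    "generate_combination_grid",
]

CONTROL_GROWTH = 0.0315  # drug-free division rate, 1/h

DEFAULT_TIMES = tuple(np.arange(0.0, 72.1, 3.0))


@dataclass(frozen=True)
class _Fixture:
    curve: HillPhenotypeCurve
    apop_frac: float
    transition_rate: float
    doses: tuple[float, ...]


def _log_doses(ec50: float, n: int = 5, lo: float = 0.25, hi: float = 8.0):
    return tuple(np.geomspace(lo * ec50, hi * ec50, n).round(4))


FIXTURES: Mapping[str, _Fixture] = {
    # strong growth inhibition, modest apoptotic death (doxorubicin-like)
    "DOX-like": _Fixture(
        HillPhenotypeCurve(ec50=20.0, hill_slope=1.5, control_growth=CONTROL_GROWTH,
                           emax_growth_inhib=0.85, emax_death_rate=0.004),
        apop_frac=0.85, transition_rate=0.035, doses=_log_doses(20.0),
    ),
    # strong, less-apoptotic death with moderate growth effect (vinorelbine-like)
    "NVB-like": _Fixture(
        HillPhenotypeCurve(ec50=30.0, hill_slope=1.2, control_growth=CONTROL_GROWTH,
                           emax_growth_inhib=0.35, emax_death_rate=0.025),
        apop_frac=0.5, transition_rate=0.045, doses=_log_doses(30.0),
    ),
    # pure growth inhibition (IGF-1R-inhibitor-like)
    "OSI-906-like": _Fixture(
        HillPhenotypeCurve(ec50=300.0, hill_slope=1.5, control_growth=CONTROL_GROWTH,
                           emax_growth_inhib=0.7, emax_death_rate=0.0),
        apop_frac=0.7, transition_rate=0.04, doses=_log_doses(300.0),
    ),
    # weaker pure growth inhibition (MEK-inhibitor-like)
    "binimetinib-like": _Fixture(
        HillPhenotypeCurve(ec50=50.0, hill_slope=1.5, control_growth=CONTROL_GROWTH,
                           emax_growth_inhib=0.3, emax_death_rate=0.0),
        apop_frac=0.7, transition_rate=0.04, doses=_log_doses(50.0),
    ),
    # pure death induction (SMAC-mimetic-like)
    "LCL161-like": _Fixture(
        HillPhenotypeCurve(ec50=150.0, hill_slope=1.5, control_growth=CONTROL_GROWTH,
                           emax_growth_inhib=0.0, emax_death_rate=0.03),
        apop_frac=0.6, transition_rate=0.04, doses=_log_doses(150.0),
    ),
    # mixed growth and death effects (PIM-inhibitor-like)
    "PIM447-like": _Fixture(
        HillPhenotypeCurve(ec50=100.0, hill_slope=1.2, control_growth=CONTROL_GROWTH,
                           emax_growth_inhib=0.5, emax_death_rate=0.012),
        apop_frac=0.6, transition_rate=0.04, doses=_log_doses(100.0),
    ),
}


@dataclass(frozen=True)
class TruthSpec:
    """Ground truth for one synthetic experiment.

    ``curves`` maps compound name to its dose-response truth; single-agent
    generators use the first entry, combination generators the first two.
    ``noise_scale`` multiplies the observation model's per-channel noise
    (0 gives noiseless tables).
    """

    curves: Mapping[str, HillPhenotypeCurve]
    apop_frac: float
    transition_rate: float
    doses: Mapping[str, tuple[float, ...]]
    observation: ObservationModel = field(default_factory=ObservationModel)
    times: tuple[float, ...] = DEFAULT_TIMES
    replicates: int = 3
    noise_scale: float = 1.0
    seed: int = 0

    def rates_for(self, compound: str, conc: float):
        return rates_at_dose(self.curves[compound], conc,
                             self.apop_frac, self.transition_rate)


def fixture_truth(
    name: str,
    seed: int = 0,
    doses: Sequence[float] | None = None,
    **overrides,
) -> TruthSpec:
    """TruthSpec for a named fixture; ``overrides`` replace TruthSpec fields."""
    fx = FIXTURES[name]
    spec = TruthSpec(
        curves={name: fx.curve},
        apop_frac=fx.apop_frac,
        transition_rate=fx.transition_rate,
        doses={name: tuple(doses) if doses is not None else fx.doses},
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def prior_central_truth(seed: int = 0, noise_scale: float = 0.2) -> TruthSpec:
    """Truth with every weakly identified parameter at its prior center.

    A mixed growth/death compound whose top-dose death rate, apopFrac and
    early->late transition rate sit at the centers of the inference priors
    (0.01 1/h, 0.5, 0.01 1/h): the model's own notion of a typical condition.
    Used to benchmark fitting modes against each other (e.g. end-point vs
    kinetic), where the answer should not hinge on an atypical truth.
    """
    ec50 = 100.0
    doses = _log_doses(ec50)
    h_top = hill_fraction(doses[-1], ec50, 1.5)
    curve = HillPhenotypeCurve(
        ec50=ec50, hill_slope=1.5, control_growth=CONTROL_GROWTH,
        emax_growth_inhib=0.6, emax_death_rate=0.01 / h_top,
    )
    return TruthSpec(
        curves={"benchmark": curve},
        apop_frac=0.5,
        transition_rate=0.01,
        doses={"benchmark": doses},
        noise_scale=noise_scale,
        seed=seed,
    )


def generate_recovery_experiment(
    seed: int,
    compound: str = "cmpd",
    replicates: int = 3,
    times: Sequence[float] = DEFAULT_TIMES,
    noise_scale: float = 1.0,
):
    """One simulation-based-calibration experiment for the kinetic fit.

    Every parameter the fit estimates is drawn independently from its
    inference prior wherever that prior is informative: per-condition death
    rate, apopFrac and early->late transition rate, plus the observation
    conversions and backgrounds (the calibration itself is uncertain).
    Division rates follow a Hill dose-response across five doses, spanning
    growth-dominant through death-dominant regimes across seeds. Under this
    design posterior credible intervals are calibrated by construction, so
    repeated fits measure the implementation, not the luck of the truth.

    Returns ``(table, rates_by_conc, observation)`` where ``rates_by_conc``
    maps each dose to its true :class:`RateParameters`.
    """
    rng = np.random.default_rng(seed)
    ec50 = 100.0
    doses = _log_doses(ec50)
    slope = float(rng.uniform(1.0, 2.0))
    emax_gi = float(rng.uniform(0.2, 0.85))
    conv = 10.0 ** rng.normal(0.0, 0.05, 3)
    bg = 0.1 * 10.0 ** rng.normal(0.0, 0.1, 3)
    observation = ObservationModel(
        conv_phase=5.0 * conv[0], conv_annexin=2.0 * conv[1],
        conv_yoyo=2.0 * conv[2],
        bg_phase=bg[0], bg_annexin=bg[1], bg_yoyo=bg[2],
    )
    spec = TruthSpec(
        curves={}, apop_frac=0.5, transition_rate=0.04, doses={},
        observation=observation, times=tuple(times), replicates=replicates,
        noise_scale=noise_scale, seed=int(rng.integers(2 ** 31)),
    )
    gen_rng = np.random.default_rng(spec.seed)
    rates_by_conc = {}
    clip_log: list = []
    frames = []
    for conc in doses:
        h = hill_fraction(conc, ec50, slope)
        params = RateParameters(
            div=CONTROL_GROWTH * (1.0 - emax_gi * h),
            death_rate=float(np.minimum(0.01 * 10 ** rng.normal(0.0, 0.5),
                                        0.15)),
            apop_frac=float(rng.uniform(0.0, 1.0)),
            transition_rate=float(np.minimum(0.01 * 10 ** rng.normal(0.0, 0.5),
                                             0.25)),
        )
        rates_by_conc[conc] = params
        frames += _rows_for_condition(
            spec, params,
            {"compound": compound, "conc": conc, "compound2": "", "conc2": 0.0},
            gen_rng, clip_log,
        )
    return _finalize(frames, clip_log), rates_by_conc, observation


def _noisy(values: np.ndarray, sd: float, rng: np.random.Generator,
           clip_log: list) -> np.ndarray:
    noisy = values + sd * rng.standard_normal(values.shape)
    clipped = np.clip(noisy, 0.0, 100.0)
    n_clip = int(np.sum(clipped != noisy))
    if n_clip:
        clip_log.append(n_clip)
    return clipped


def _rows_for_condition(
    truth: TruthSpec,
    params,
    meta: dict,
    rng: np.random.Generator,
    clip_log: list,
) -> list[pd.DataFrame]:
    obs = truth.observation
    traj = simulate_trajectory(params, np.asarray(truth.times))
    clean = observables(traj, obs)
    frames = []
    for rep in range(1, truth.replicates + 1):
        df = clean.copy()
        for chan, sd in zip(("phase_pct", "annexin_pct", "yoyo_pct"),
                            obs.noise_sd * truth.noise_scale):
            if sd > 0:
                df[chan] = _noisy(df[chan].to_numpy(), sd, rng, clip_log)
        df["replicate"] = rep
        for k, v in meta.items():
            df[k] = v
        frames.append(df)
    return frames


def _finalize(frames: list[pd.DataFrame], clip_log: list) -> pd.DataFrame:
    table = pd.concat(frames, ignore_index=True)[TIDY_COLUMNS]
    table.attrs["n_clipped"] = int(sum(clip_log))
    return table


def generate_single_agent(truth: TruthSpec) -> pd.DataFrame:
    """Tidy three-channel table for one compound across its dose list."""
    rng = np.random.default_rng(truth.seed)
    compound = next(iter(truth.curves))
    clip_log: list = []
    frames = []
    for conc in truth.doses[compound]:
        params = truth.rates_for(compound, conc)
        frames += _rows_for_condition(
            truth, params,
            {"compound": compound, "conc": conc, "compound2": "", "conc2": 0.0},
            rng, clip_log,
        )
    return _finalize(frames, clip_log)


def generate_viability_assay(
    truth: TruthSpec,
    t: float = 72.0,
    noise_sd: float = 0.02,
    include_zero: bool = True,
) -> pd.DataFrame:
    """Dose-viability table (conc, replicate, viability) at end time ``t``.

    Viability is live-cell number relative to untreated control plus Gaussian
    noise, floored at a small positive value (as a plate reader would never
    report nonpositive signal).
    """
    rng = np.random.default_rng(truth.seed)
    compound = next(iter(truth.curves))
    curve = truth.curves[compound]
    doses = list(truth.doses[compound])
    if include_zero and 0.0 not in doses:
        doses = [0.0] + doses
    rows = []
    for conc in doses:
        v = viability_at_dose(curve, conc, t)
        for rep in range(1, truth.replicates + 1):
            noisy = v + noise_sd * rng.standard_normal() * truth.noise_scale
            rows.append((conc, rep, max(noisy, 1e-4)))
    return pd.DataFrame(rows, columns=["conc", "replicate", "viability"])


def generate_combination_grid(
    truth_a: TruthSpec,
    truth_b: TruthSpec,
    death_synergy: float = 1.0,
    growth_combination: str = "additive",
    times: Sequence[float] | None = None,
    seed: int | None = None,
) -> DoseGrid:
    """Rectangular two-compound grid generated from the combination null.

    Rates per cell come from :func:`growthdeath.interaction.combo_rates`;
    ``death_synergy`` scales the combined death rate wherever both compounds
    are present (1.0 reproduces the additive null exactly). Shared apopFrac,
    transition rate, observation model, replicates and noise are taken from
    ``truth_a``. Dose lists gain a 0 edge automatically.
    """
    name_a = next(iter(truth_a.curves))
    name_b = next(iter(truth_b.curves))
    curve_a = truth_a.curves[name_a]
    curve_b = truth_b.curves[name_b]
    doses_a = [0.0] + [c for c in truth_a.doses[name_a] if c > 0]
    doses_b = [0.0] + [c for c in truth_b.doses[name_b] if c > 0]
    rng = np.random.default_rng(truth_a.seed if seed is None else seed)
    t_grid = replace(truth_a, times=tuple(times)) if times is not None else truth_a
    clip_log: list = []
    frames = []
    for ca in doses_a:
        for cb in doses_b:
            params = combo_rates(curve_a, curve_b, ca, cb,
                                 truth_a.apop_frac, truth_a.transition_rate,
                                 growth_combination=growth_combination)
            if death_synergy != 1.0 and ca > 0 and cb > 0:
                params = replace(params,
                                 death_rate=params.death_rate * death_synergy)
            frames += _rows_for_condition(
                t_grid, params,
                {"compound": name_a, "conc": ca,
                 "compound2": name_b, "conc2": cb},
                rng, clip_log,
            )
    return DoseGrid(table=_finalize(frames, clip_log))
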