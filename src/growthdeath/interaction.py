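"""Drug-combination analysis: Bliss on viability vs growth/death-rate additivity.

Two views of the same dose grid:

* classical Bliss independence applied to the proportional decrease in
  measured viability (confluence relative to the untreated control), and
* a mechanistic null in which the compounds' growth-rate reductions add (which
  is exactly Bliss independence at the live-cell viability level, since rate
  effects add in the exponent) and their death rates add.

Deviation maps are signed observed-minus-predicted decreases, so synergy is
positive and antagonism negative. Note that when dead cells remain in the
confluence signal, a genuinely additive growth-only + death-only pair
*necessarily* deviates from viability-Bliss (the dead-cell term breaks the
multiplicativity of viabilities), which is how a rate-additive combination can
masquerade as an interaction when judged by viability alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import kinetics
from .dose_response import HillPhenotypeCurve
from .inference import (
    CHANNELS,
    _gaussian_ll,
    _predict_channels,
    condition_moment_estimates,
    validate_experiment_table,
)
from .kinetics import RateParameters
from .mcmc import ParamBlock, ParamSet, PosteriorSamples, run_fit
from .priors import HalfNormal, LogNormal10, LogUniform10, Uniform

__all__ = [
    "DoseGrid",
    "DeviationMap",
    "bliss_predicted_decrease",
    "viability_deviation_map",
    "combo_rates",
    "fit_combination",
    "model_deviation_map",
    "posterior_mean_curves",
]

GrowthCombination = Literal["additive", "independence"]


def bliss_predicted_decrease(dec_a, dec_b):
    """Bliss-independent combined proportional decrease: a + b - a*b.

    Both arguments are proportional decreases in viability, in [0, 1];
    commutative, monotone in each argument, with identity 0 and absorbing
    element 1.
    """
    a = np.asarray(dec_a, dtype=float)
    b = np.asarray(dec_b, dtype=float)
    if np.any((a < 0) | (a > 1)) or np.any((b < 0) | (b > 1)):
        raise ValueError("proportional decreases must lie in [0, 1]")
    out = a + b - a * b
    if np.ndim(dec_a) == 0 and np.ndim(dec_b) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class DoseGrid:
    """A rectangular two-compound dose grid of tidy measurements.

    ``table`` holds every (concA, concB) cell, including the single-agent
    edges and the (0, 0) control, in the same tidy schema as single-agent
    experiments (compound/conc for drug A, compound2/conc2 for drug B).
    """

    table: pd.DataFrame
    compound_a: str = field(init=False)
    compound_b: str = field(init=False)
    doses_a: np.ndarray = field(init=False)
    doses_b: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        df = validate_experiment_table(self.table)
        names_a = df["compound"].unique()
        names_b = df["compound2"].unique()
        if len(names_a) != 1 or len(names_b) != 1 or names_b[0] == "":
            raise ValueError(
                "a dose grid holds exactly one compound pair "
                "(columns compound/compound2)"
            )
        object.__setattr__(self, "table", df)
        object.__setattr__(self, "compound_a", str(names_a[0]))
        object.__setattr__(self, "compound_b", str(names_b[0]))
        da = np.sort(df["conc"].unique())
        db = np.sort(df["conc2"].unique())
        cells = set(map(tuple, df[["conc", "conc2"]].drop_duplicates().to_numpy()))
        expected = {(a, b) for a in da for b in db}
        if cells != expected:
            raise ValueError("dose grid is not rectangular")
        if da[0] != 0 or db[0] != 0:
            raise ValueError("dose grid must include the (0, 0) control "
                             "and single-agent edges")
        object.__setattr__(self, "doses_a", da)
        object.__setattr__(self, "doses_b", db)

    def times_near(self, t: float, n: int = 1) -> np.ndarray:
        """The ``n`` measured time points closest to ``t``."""
        times = np.unique(self.table["time_h"].to_numpy())
        order = np.argsort(np.abs(times - t), kind="stable")
        return np.sort(times[order[:n]])

    def channel_matrix(self, t: float, channel: str = "phase_pct") -> pd.DataFrame:
        """Replicate-mean channel values at the time closest to ``t``.

        Rows are compound-A doses, columns compound-B doses.
        """
        if channel not in CHANNELS:
            raise ValueError(f"unknown channel {channel!r}")
        t_near = self.times_near(t, 1)[0]
        sub = self.table[self.table["time_h"] == t_near]
        mat = sub.pivot_table(index="conc", columns="conc2", values=channel,
                              aggfunc="mean")
        return mat.reindex(index=self.doses_a, columns=self.doses_b)


@dataclass(frozen=True)
class DeviationMap:
    """Signed observed-minus-predicted decrease over a dose grid.

    Positive entries indicate apparent synergy (more decrease than the null
    predicts), negative antagonism. Single-agent edges are zero by
    construction for the Bliss map.
    """

    values: pd.DataFrame  # index: compound-A doses, columns: compound-B doses
    kind: str

    @property
    def max_deviation(self) -> float:
        return float(np.nanmax(self.values.to_numpy()))

    @property
    def min_deviation(self) -> float:
        return float(np.nanmin(self.values.to_numpy()))

    @property
    def max_abs_deviation(self) -> float:
        return float(np.nanmax(np.abs(self.values.to_numpy())))

    def interior(self) -> np.ndarray:
        """Deviations at cells where both compounds are present."""
        return self.values.to_numpy()[1:, 1:]


def _decrease_matrix(grid: DoseGrid, t: float, channel: str) -> pd.DataFrame:
    mat = grid.channel_matrix(t, channel)
    control = mat.iloc[0, 0]
    if not np.isfinite(control) or control <= 0:
        raise ValueError("control (0, 0) measurement missing or nonpositive")
    dec = 1.0 - mat / control
    return dec.clip(lower=0.0, upper=1.0)


def viability_deviation_map(
    grid: DoseGrid, t: float = 72.0, channel: str = "phase_pct",
    n_times: int = 3,
) -> DeviationMap:
    """Deviation from Bliss independence on measured viability.

    Viability is the replicate-mean channel value (phase confluence by
    default) normalized to the (0, 0) control at the same time; the Bliss
    prediction for each cell combines the single-agent decreases read off the
    grid edges. To tame read noise the per-scan deviation map is averaged
    over the ``n_times`` scans closest to ``t`` (deviations drift slowly in
    time while the per-scan noise is independent); edges stay exactly zero.
    """
    maps = []
    for ti in grid.times_near(t, n_times):
        dec = _decrease_matrix(grid, ti, channel)
        dec_a = dec.iloc[:, 0].to_numpy()  # compound A alone (concB = 0)
        dec_b = dec.iloc[0, :].to_numpy()  # compound B alone
        pred = bliss_predicted_decrease(dec_a[:, None], dec_b[None, :])
        maps.append(dec.to_numpy() - pred)
    dec0 = _decrease_matrix(grid, t, channel)
    dev = pd.DataFrame(np.mean(maps, axis=0), index=dec0.index,
                       columns=dec0.columns)
    return DeviationMap(values=dev, kind="bliss_viability")


def combo_rates(
    curve_a: HillPhenotypeCurve,
    curve_b: HillPhenotypeCurve,
    conc_a: float,
    conc_b: float,
    apop_frac: float,
    transition_rate: float,
    growth_combination: GrowthCombination = "additive",
) -> RateParameters:
    """Null-interaction rates for a dose pair.

    Death rates add. Growth-rate reductions combine additively by default
    (``div = g0 max(0, 1 - IA - IB)``), which makes live-cell viabilities
    exactly multiplicative -- Bliss independence on viability; the
    ``"independence"`` option instead combines the inhibition fractions as
    independent events (``I = IA + IB - IA IB``). Reduces to the single-agent
    rates when the other concentration is zero (the curves must share the
    same drug-free growth rate).
    """
    if abs(curve_a.control_growth - curve_b.control_growth) > 1e-12:
        raise ValueError("combination curves must share control_growth")
    g0 = curve_a.control_growth
    ia = curve_a.growth_inhibition(conc_a)
    ib = curve_b.growth_inhibition(conc_b)
    if growth_combination == "additive":
        inhib = min(ia + ib, 1.0)
    elif growth_combination == "independence":
        inhib = ia + ib - ia * ib
    else:
        raise ValueError(f"unknown growth_combination {growth_combination!r}")
    return RateParameters(
        div=g0 * (1.0 - inhib),
        death_rate=curve_a.death_rate(conc_a) + curve_b.death_rate(conc_b),
        apop_frac=apop_frac,
        transition_rate=transition_rate,
    )


def _hill_matrix(conc: np.ndarray, ec50: np.ndarray, slope: np.ndarray) -> np.ndarray:
    """h(conc) for walker arrays; conc (C,), ec50/slope (K,) -> (K, C)."""
    with np.errstate(divide="ignore"):
        logc = np.log(np.where(conc > 0, conc, 1.0))
    h = 1.0 / (1.0 + np.exp(-slope[:, None] * (logc[None, :] -
                                               np.log(ec50)[:, None])))
    return np.where(conc[None, :] > 0, h, 0.0)


def fit_combination(
    grid: DoseGrid,
    seed: int = 0,
    growth_combination: GrowthCombination = "additive",
    conversion_centers: Sequence[float] = (5.0, 2.0, 2.0),
    walkers: int = 64,
    tune: int = 1000,
    draws: int = 400,
    min_ess: float = 200.0,
    retry: bool = True,
) -> PosteriorSamples:
    """Joint fit of the additive growth/death model to a three-channel grid.

    Per compound: EC50 (log-uniform over its dose range), Hill slope
    (log-normal median 1, sd 1 log10), maximal growth inhibition (Beta(1,1)),
    maximal death rate (log-normal median 0.01 1/h, sd 0.5 log10). Shared:
    drug-free growth rate (log-normal median 10^-1.5 1/h, sd 0.1 log10) --
    cells undergo no death without drug -- plus one apopFrac and one early->
    late transition rate d across all conditions, and the channel
    conversion/background/noise parameters.
    """
    df = grid.table
    cells = sorted(set(map(tuple, df[["conc", "conc2"]].to_numpy())))
    cell_index = {c: i for i, c in enumerate(cells)}
    times = np.unique(df["time_h"].to_numpy())
    time_index = {t: i for i, t in enumerate(times)}
    cond_idx = np.array([cell_index[c] for c in
                         df[["conc", "conc2"]].itertuples(index=False, name=None)])
    time_idx = np.array([time_index[t] for t in df["time_h"]])
    y = df[CHANNELS].to_numpy(dtype=float)
    ca = np.array([c[0] for c in cells])
    cb = np.array([c[1] for c in cells])

    def dose_prior(doses: np.ndarray) -> LogUniform10:
        pos = doses[doses > 0]
        return LogUniform10(pos.min() / 10.0, pos.max() * 10.0)

    na, nb = grid.compound_a, grid.compound_b
    blocks = []
    for name, doses in ((na, grid.doses_a), (nb, grid.doses_b)):
        blocks += [
            ParamBlock(f"ec50[{name}]", dose_prior(doses)),
            ParamBlock(f"hillSlope[{name}]", LogNormal10(1.0, 1.0)),
            ParamBlock(f"emaxGrowthInhib[{name}]", Uniform(0.0, 1.0)),
            ParamBlock(f"emaxDeathRate[{name}]", LogNormal10(0.01, 0.5)),
        ]
    blocks += [
        ParamBlock("g0", LogNormal10(10.0 ** -1.5, 0.1)),
        ParamBlock("apopFrac", Uniform(0.0, 1.0)),
        ParamBlock("d", LogNormal10(0.01, 0.5)),
    ]
    for i, chan in enumerate(("phase", "annexin", "yoyo")):
        blocks.append(ParamBlock(f"conv_{chan}",
                                 LogNormal10(conversion_centers[i], 0.05)))
    blocks.append(ParamBlock("background", LogNormal10(0.1, 0.1), size=3,
                             labels=("bg_phase", "bg_annexin", "bg_yoyo")))
    blocks.append(ParamBlock("noise", HalfNormal(1.0), size=3,
                             labels=("sd_phase", "sd_annexin", "sd_yoyo")))
    pset = ParamSet(blocks)

    # seed the mode search from control/edge moment estimates
    conv0 = np.asarray(conversion_centers, dtype=float)
    bg0 = np.full(3, 0.1)
    groups = dict(tuple(df.groupby(["conc", "conc2"], sort=True)))
    g0_hat, _, _ = condition_moment_estimates(groups[(0.0, 0.0)], conv0, bg0)
    g0_hat = float(np.clip(g0_hat, 0.015, 0.06))
    init = {"g0": np.array([g0_hat]), "apopFrac": np.array([0.5]),
            "d": np.array([0.04]),
            "conv_phase": conv0[:1], "conv_annexin": conv0[1:2],
            "conv_yoyo": conv0[2:3], "background": bg0,
            "noise": np.full(3, 0.3)}
    for name, doses, edge in ((na, grid.doses_a, lambda top: (top, 0.0)),
                              (nb, grid.doses_b, lambda top: (0.0, top))):
        top = doses[-1]
        dv, dr, _ = condition_moment_estimates(groups[edge(top)], conv0, bg0)
        pos = doses[doses > 0]
        init[f"ec50[{name}]"] = np.array([float(np.exp(np.mean(np.log(pos))))])
        init[f"hillSlope[{name}]"] = np.array([1.0])
        init[f"emaxGrowthInhib[{name}]"] = np.array(
            [float(np.clip(1.0 - dv / g0_hat, 0.02, 0.98))])
        init[f"emaxDeathRate[{name}]"] = np.array(
            [float(np.clip(dr, 5e-4, 0.3))])

    def loglik(x: dict[str, np.ndarray]) -> np.ndarray:
        ha = _hill_matrix(ca, x[f"ec50[{na}]"][:, 0], x[f"hillSlope[{na}]"][:, 0])
        hb = _hill_matrix(cb, x[f"ec50[{nb}]"][:, 0], x[f"hillSlope[{nb}]"][:, 0])
        ia = x[f"emaxGrowthInhib[{na}]"][:, [0]] * ha
        ib = x[f"emaxGrowthInhib[{nb}]"][:, [0]] * hb
        if growth_combination == "additive":
            inhib = np.minimum(ia + ib, 1.0)
        else:
            inhib = ia + ib - ia * ib
        g0 = x["g0"][:, [0]]
        rates = {
            "div": g0 * (1.0 - inhib),
            "deathRate": x[f"emaxDeathRate[{na}]"][:, [0]] * ha
            + x[f"emaxDeathRate[{nb}]"][:, [0]] * hb,
            "apopFrac": np.broadcast_to(x["apopFrac"][:, [0]], ia.shape),
            "d": np.broadcast_to(x["d"][:, [0]], ia.shape),
        }
        conv = np.concatenate(
            [x["conv_phase"], x["conv_annexin"], x["conv_yoyo"]], axis=-1
        )
        pred = _predict_channels(rates, times, conv, x["background"])
        pred_rows = pred[:, cond_idx, time_idx, :]
        return _gaussian_ll(y, pred_rows, x["noise"])

    # seed the weakly identified transition rate from a coarse likelihood scan
    cand = np.array([0.003, 0.01, 0.03, 0.1, 0.25])
    scan = {k: np.tile(v, (cand.size, 1)) for k, v in init.items()}
    scan["d"] = cand[:, None]
    init["d"] = np.array([cand[int(np.argmax(loglik(scan)))]])

    gate = [lab for lab in pset.labels
            if lab.startswith(("emaxGrowthInhib", "emaxDeathRate", "g0"))]
    return run_fit(
        pset, loglik, seed=seed, walkers=walkers, tune=tune, draws=draws,
        min_ess=min_ess, retry=retry, gate_labels=gate, init_values=init,
        meta={"mode": "combination", "compound_a": na, "compound_b": nb,
              "growth_combination": growth_combination},
    )


def posterior_mean_curves(
    post: PosteriorSamples,
) -> tuple[HillPhenotypeCurve, HillPhenotypeCurve, dict]:
    """Posterior-mean Hill curves and shared parameters from a combination fit."""
    na, nb = post.meta["compound_a"], post.meta["compound_b"]
    g0 = post.mean("g0")
    curves = []
    for name in (na, nb):
        curves.append(HillPhenotypeCurve(
            ec50=float(np.exp(np.mean(np.log(post.draws(f"ec50[{name}]"))))),
            hill_slope=post.mean(f"hillSlope[{name}]"),
            control_growth=g0,
            emax_growth_inhib=post.mean(f"emaxGrowthInhib[{name}]"),
            emax_death_rate=post.mean(f"emaxDeathRate[{name}]"),
        ))
    shared = {
        "apop_frac": post.mean("apopFrac"),
        "d": post.mean("d"),
        "conv": np.array([post.mean("conv_phase"), post.mean("conv_annexin"),
                          post.mean("conv_yoyo")]),
        "bg": np.array([post.mean("bg_phase"), post.mean("bg_annexin"),
                        post.mean("bg_yoyo")]),
    }
    return curves[0], curves[1], shared


def model_deviation_map(
    grid: DoseGrid,
    post: PosteriorSamples,
    t: float = 72.0,
    channel: str = "phase_pct",
    n_times: int = 3,
) -> DeviationMap:
    """Deviation of the measurements from the fitted additive rate model.

    Observed proportional decrease minus the posterior-mean model's predicted
    decrease, per grid cell, averaged over the ``n_times`` scans closest to
    ``t`` (as for the Bliss map); approximately zero everywhere when the
    additive model describes the data.
    """
    curve_a, curve_b, shared = posterior_mean_curves(post)
    chan_idx = CHANNELS.index(channel)
    conv, bg = shared["conv"][chan_idx], shared["bg"][chan_idx]
    maps = []
    for ti in grid.times_near(t, n_times):
        dec_obs = _decrease_matrix(grid, ti, channel)
        pred = np.empty((grid.doses_a.size, grid.doses_b.size))
        for i, a in enumerate(grid.doses_a):
            for j, b in enumerate(grid.doses_b):
                params = combo_rates(
                    curve_a, curve_b, a, b, shared["apop_frac"], shared["d"],
                    growth_combination=post.meta["growth_combination"],
                )
                state = kinetics.analytic_state(params, ti)
                signal = [state.total, state.E + state.Da,
                          state.Da + state.Dn][chan_idx]
                pred[i, j] = conv * signal + bg
        pred_dec = np.clip(1.0 - pred / pred[0, 0], 0.0, 1.0)
        maps.append(dec_obs.to_numpy() - pred_dec)
    dec0 = _decrease_matrix(grid, t, channel)
    dev = pd.DataFrame(np.mean(maps, axis=0), index=dec0.index,
                       columns=dec0.columns)
    return DeviationMap(values=dev, kind="rate_model")
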