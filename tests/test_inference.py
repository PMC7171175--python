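"""Likelihood, priors and rate fitting on three-channel tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from growthdeath.inference import (
    default_priors,
    endpoint_reduction,
    fit_experiment,
    log_likelihood,
    validate_experiment_table,
)
from growthdeath.kinetics import ObservationModel, RateParameters, state_arrays
from growthdeath.synthetic import (
    TruthSpec,
    fixture_truth,
    generate_single_agent,
    prior_central_truth,
)
from growthdeath.dose_response import HillPhenotypeCurve


def toy_table(noise=None, times=(0.0, 24.0, 48.0, 60.0, 72.0)):
    """Single-condition table whose channels follow the model exactly."""
    p = RateParameters(0.02, 0.01, 0.6, 0.05)
    obs = ObservationModel()
    L, E, Da, Dn = state_arrays(p.div, p.death_rate, p.apop_frac,
                               p.transition_rate, np.array(times))
    rows = []
    for i, t in enumerate(times):
        rows.append({
            "compound": "drugX", "conc": 1.0, "compound2": "", "conc2": 0.0,
            "time_h": t, "replicate": 1,
            "phase_pct": obs.conv_phase * (L + E + Da + Dn)[i] + obs.bg_phase,
            "annexin_pct": obs.conv_annexin * (E + Da)[i] + obs.bg_annexin,
            "yoyo_pct": obs.conv_yoyo * (Da + Dn)[i] + obs.bg_yoyo,
        })
    df = pd.DataFrame(rows)
    if noise is not None:
        rng = np.random.default_rng(0)
        for c in ("phase_pct", "annexin_pct", "yoyo_pct"):
            # keep the perturbed values inside the percent-area schema
            df[c] = np.abs(df[c] + noise * rng.standard_normal(len(df)))
    return df, {("drugX", 1.0, "", 0.0): p}, obs


class TestValidation:
    def test_missing_column_named(self):
        df, _, _ = toy_table()
        with pytest.raises(ValueError, match="time_h"):
            validate_experiment_table(df.drop(columns=["time_h"]))

    def test_out_of_range_percent_reports_rows(self):
        df, _, _ = toy_table()
        df.loc[2, "phase_pct"] = 150.0
        with pytest.raises(ValueError, match="phase_pct"):
            validate_experiment_table(df)

    def test_negative_time_rejected(self):
        df, _, _ = toy_table()
        df.loc[0, "time_h"] = -3.0
        with pytest.raises(ValueError, match="time_h"):
            validate_experiment_table(df)


class TestLogLikelihood:
    def test_matches_per_point_oracle(self):
        df, params, obs = toy_table(noise=0.3)
        ll = log_likelihood(df, params, obs)
        # brute-force: per-record normal densities around the noiseless table
        clean, _, _ = toy_table()
        brute = 0.0
        for c, sd in zip(("phase_pct", "annexin_pct", "yoyo_pct"),
                         obs.noise_sd):
            brute += stats.norm.logpdf(df[c], loc=clean[c], scale=sd).sum()
        assert ll == pytest.approx(brute, rel=1e-12)

    def test_record_order_invariance(self):
        df, params, obs = toy_table(noise=0.3)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert log_likelihood(df, params, obs) == pytest.approx(
            log_likelihood(shuffled, params, obs))

    def test_doubling_noise_on_perfect_fit_costs_n_log_two(self):
        df, params, obs = toy_table()
        wide = ObservationModel(sd_phase=obs.sd_phase * 2,
                                sd_annexin=obs.sd_annexin * 2,
                                sd_yoyo=obs.sd_yoyo * 2)
        delta = log_likelihood(df, params, obs) - log_likelihood(df, params, wide)
        assert delta == pytest.approx(3 * len(df) * np.log(2.0))

    def test_missing_condition_rejected(self):
        df, _, obs = toy_table()
        with pytest.raises(ValueError, match="missing RateParameters"):
            log_likelihood(df, {}, obs)


class TestDefaultPriors:
    def test_paper_prior_centers(self):
        priors = default_priors()
        assert priors["deathRate"].median == 0.01
        assert priors["d"].median == 0.01
        assert priors["background"].median == 0.1
        assert (priors["div"].lo, priors["div"].hi) == (0.0, 0.35)
        assert (priors["apopFrac"].lo, priors["apopFrac"].hi) == (0.0, 1.0)

    def test_div_prior_has_no_mass_above_bound(self):
        priors = default_priors()
        assert priors["div"].x_from_u(100.0) <= 0.35

    def test_prior_predictive_channels_plausible(self):
        # typical prior-central kinetics stay inside the percent-area range
        priors = default_priors()
        p = RateParameters(0.03, priors["deathRate"].median, 0.5,
                           priors["d"].median)
        L, E, Da, Dn = state_arrays(p.div, p.death_rate, p.apop_frac,
                                   p.transition_rate, np.arange(0, 72.1, 3.0))
        phase = 5.0 * (L + E + Da + Dn) + 0.1
        assert np.all((phase >= 0) & (phase <= 100))


class TestEndpointReduction:
    def test_keeps_exactly_two_times(self):
        truth = fixture_truth("PIM447-like", seed=5)
        table = generate_single_agent(truth)
        reduced = endpoint_reduction(table)
        per_cond = reduced.groupby("conc")["time_h"].nunique()
        assert (per_cond == 2).all()
        assert set(reduced["time_h"]) == {0.0, 72.0}

    def test_single_time_point_rejected(self):
        df, _, _ = toy_table(times=(24.0,))
        with pytest.raises(ValueError, match="single time point"):
            endpoint_reduction(df)


class TestFitExperiment:
    def test_recovers_truth_on_low_noise_single_condition(self, quick_fit_opts):
        curve = HillPhenotypeCurve(ec50=10.0, hill_slope=1.5,
                                   control_growth=0.0315,
                                   emax_growth_inhib=0.5,
                                   emax_death_rate=0.012)
        truth = TruthSpec(curves={"drugX": curve}, apop_frac=0.6,
                          transition_rate=0.02, doses={"drugX": (40.0,)},
                          times=tuple(np.arange(0.0, 72.1, 6.0)),
                          noise_scale=0.25, seed=9)
        table = generate_single_agent(truth)
        post = fit_experiment(table, seed=10, **quick_fit_opts)
        pt = truth.rates_for("drugX", 40.0)
        assert post.mean("div[drugX@40]") == pytest.approx(pt.div, rel=0.05)
        assert post.mean("deathRate[drugX@40]") == pytest.approx(
            pt.death_rate, rel=0.10)

    def test_death_free_truth_shrinks_to_prior_floor(self, quick_fit_opts):
        truth = fixture_truth("OSI-906-like", seed=6,
                              doses=(2400.0,), noise_scale=0.5)
        table = generate_single_agent(truth)
        post = fit_experiment(table, seed=11, **quick_fit_opts)
        # no death signal: posterior death rate collapses well below the
        # prior median
        assert post.mean("deathRate[OSI-906-like@2400]") < 0.005

    def test_requires_two_time_points(self):
        df, _, _ = toy_table(times=(24.0,))
        with pytest.raises(ValueError, match="fewer than 2 time points"):
            fit_experiment(df)

    def test_posterior_respects_domains(self, quick_fit_opts):
        truth = prior_central_truth(seed=3)
        truth = TruthSpec(curves=truth.curves, apop_frac=truth.apop_frac,
                          transition_rate=truth.transition_rate,
                          doses={"benchmark": truth.doses["benchmark"][-1:]},
                          noise_scale=0.5, seed=3,
                          times=tuple(np.arange(0.0, 72.1, 12.0)))
        table = generate_single_agent(truth)
        post = fit_experiment(table, seed=12, **quick_fit_opts)
        lab = f"benchmark@{truth.doses['benchmark'][0]:g}"
        assert np.all(post.draws(f"div[{lab}]") >= 0)
        assert np.all(post.draws(f"div[{lab}]") <= 0.35)
        f = post.draws(f"apopFrac[{lab}]")
        assert np.all((f >= 0) & (f <= 1))
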