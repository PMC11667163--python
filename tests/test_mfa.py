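import copy

import numpy as np
import pytest

from adipoflux.emu import TracerSpec, simulate_mids
from adipoflux.measurements import MID
from adipoflux.mfa import (
    FluxModel,
    RateTarget,
    TracerExperiment,
    chi2_interval,
    fit_fluxes,
    flux_confidence_interval,
    ssr,
)
from adipoflux.network import FluxVector, load_network

SD = 0.003


def cycle_experiment(net, fluxes, tracer, noise_sd=0.0, seed=None, sd=SD,
                     targets=("CIT.c", "AKG.c", "SUC.c", "MAL.c")):
    """One tracer experiment on the condensation-cycle toy network."""
    rng = np.random.default_rng(seed)
    sim = simulate_mids(net, fluxes, tracer, list(targets))
    mids = []
    for emu, clean in sim.items():
        noisy = clean.copy()
        if noise_sd:
            noisy = np.clip(noisy + rng.normal(0, noise_sd, noisy.shape), 0, None)
            noisy /= noisy.sum()
        mids.append(MID(emu.species, "full", emu.size, noisy, np.full(emu.size + 1, sd)))
    rates = [
        RateTarget("substrate", {"u": 1.0}, fluxes.net["u"], 0.25),
        RateTarget("anaplerosis", {"an": 1.0}, fluxes.net["an"], 0.1),
    ]
    return TracerExperiment(tracer, mids, rates)


@pytest.fixture(scope="module")
def cycle_setup(toy_cycle, toy_cycle_fluxes):
    tracer = TracerSpec("AC.ext", (1, 2), purity=0.99, name="acetyl")
    exp = cycle_experiment(toy_cycle, toy_cycle_fluxes, tracer)
    return toy_cycle, toy_cycle_fluxes, tracer, exp


class TestSSR:
    def test_noise_free_measurements_give_zero_ssr(self, cycle_setup):
        net, fluxes, _, exp = cycle_setup
        assert ssr(net, fluxes, [exp]) < 1e-18

    def test_invariant_to_experiment_order(self, toy_cycle, toy_cycle_fluxes):
        t1 = TracerSpec("AC.ext", (1, 2), purity=0.99)
        t2 = TracerSpec("Y.ext", (1, 2, 3, 4), purity=0.99)
        e1 = cycle_experiment(toy_cycle, toy_cycle_fluxes, t1, noise_sd=0.003, seed=1)
        e2 = cycle_experiment(toy_cycle, toy_cycle_fluxes, t2, noise_sd=0.003, seed=2)
        assert ssr(toy_cycle, toy_cycle_fluxes, [e1, e2]) == pytest.approx(
            ssr(toy_cycle, toy_cycle_fluxes, [e2, e1]))

    def test_single_channel_perturbation_changes_ssr_predictably(self, cycle_setup):
        net, fluxes, tracer, exp = cycle_setup
        model = FluxModel(net, [exp])
        base = model.ssr_at(fluxes)
        perturbed = copy.deepcopy(exp)
        mid = perturbed.mids[0]
        # +1 sd on one channel above M0; the residual moves from r to r-1
        sim = simulate_mids(net, fluxes, tracer, [mid.metabolite])
        sim_vec = list(sim.values())[0]
        r = (sim_vec[2] - mid.fractions[2]) / mid.sd[2]
        mid.fractions[2] += mid.sd[2]
        expected_delta = (r - 1.0) ** 2 - r ** 2
        new = FluxModel(net, [perturbed]).ssr_at(fluxes)
        assert new - base == pytest.approx(expected_delta, abs=1e-9)


class TestChi2:
    def test_interval_against_inverse_cdf_oracle(self):
        lo, hi = chi2_interval(10, alpha=0.01)
        # frozen from the chi-square inverse CDF at 0.005 / 0.995, 10 dof
        assert lo == pytest.approx(2.15586, abs=1e-4)
        assert hi == pytest.approx(25.18818, abs=1e-4)

    def test_ssr_at_expectation_accepted(self):
        lo, hi = chi2_interval(10, alpha=0.01)
        assert lo < 10.0 < hi

    def test_overparameterized_model_rejected(self):
        with pytest.raises(ValueError, match="over-parameterized"):
            chi2_interval(0)


class TestFit:
    def test_zero_noise_fit_recovers_exactly(self, cycle_setup):
        net, fluxes, tracer, exp = cycle_setup
        fit = fit_fluxes(net, [exp], n_restarts=3, seed=4)
        assert fit.ssr < 1e-6
        for rid, truth in fluxes.net.items():
            assert fit.fluxes.net[rid] == pytest.approx(truth, abs=0.05)
        assert fit.n_restarts == 3
        assert len(fit.restart_ssrs) == 3
        assert fit.ssr == min(fit.restart_ssrs)

    def test_default_restart_count_is_twenty(self):
        import inspect

        assert inspect.signature(fit_fluxes).parameters["n_restarts"].default == 20
        assert inspect.signature(FluxModel.fit).parameters["n_restarts"].default == 20

    def test_deterministic_under_fixed_seed(self, cycle_setup):
        net, fluxes, tracer, _ = cycle_setup
        exp = cycle_experiment(net, fluxes, tracer, noise_sd=0.003, seed=9)
        fit1 = fit_fluxes(net, [exp], n_restarts=3, seed=42)
        fit2 = fit_fluxes(net, [exp], n_restarts=3, seed=42)
        np.testing.assert_array_equal(fit1.params, fit2.params)
        assert fit1.restart_ssrs == fit2.restart_ssrs

    def test_noisy_fit_recovers_within_tolerance(self, cycle_setup):
        net, fluxes, tracer, _ = cycle_setup
        exp = cycle_experiment(net, fluxes, tracer, noise_sd=0.003, seed=5)
        fit = fit_fluxes(net, [exp], n_restarts=3, seed=6)
        ok, interval = fit.chi2_test(alpha=0.01)
        assert ok, (fit.ssr, interval)
        assert fit.fluxes.net["u"] == pytest.approx(fluxes.net["u"], rel=0.1)


class TestConfidenceIntervals:
    def test_point_estimate_inside_ci(self, cycle_setup):
        net, fluxes, tracer, _ = cycle_setup
        exp = cycle_experiment(net, fluxes, tracer, noise_sd=0.003, seed=11)
        fit = fit_fluxes(net, [exp], n_restarts=3, seed=12)
        ci = flux_confidence_interval(fit, "an")
        assert ci.lower <= fit.fluxes.net["an"] <= ci.upper

    def test_unidentifiable_exchange_reported_unbounded(self):
        net = load_network("toy_reversible")
        fluxes = FluxVector({"u": 5.0, "x": 5.0, "d": 5.0, "s": 10.0}, {"x": 3.0})
        tracer = TracerSpec("A.ext", (1, 2), purity=0.99)
        # measuring only the downstream pool leaves the exchange magnitude free
        sim = simulate_mids(net, fluxes, tracer, ["B.c"])
        mids = [MID("B.c", "full", 2, v, np.full(3, SD)) for v in sim.values()]
        rates = [RateTarget("uptake", {"u": 1.0}, 5.0, 0.1),
                 RateTarget("dilution", {"d": 1.0}, 5.0, 0.1)]
        fit = fit_fluxes(net, [TracerExperiment(tracer, mids, rates)],
                         n_restarts=2, seed=3)
        ci = fit.confidence_interval("x", kind="exchange")
        assert ci.upper_open

    def test_ci_width_shrinks_with_smaller_measurement_sd(self, cycle_setup):
        net, fluxes, tracer, _ = cycle_setup
        wide_exp = cycle_experiment(net, fluxes, tracer, noise_sd=0.0, sd=0.006)
        tight_exp = cycle_experiment(net, fluxes, tracer, noise_sd=0.0, sd=0.003)
        ci_wide = fit_fluxes(net, [wide_exp], n_restarts=2, seed=1).confidence_interval("an")
        ci_tight = fit_fluxes(net, [tight_exp], n_restarts=2, seed=1).confidence_interval("an")
        assert (ci_tight.upper - ci_tight.lower) < (ci_wide.upper - ci_wide.lower)

    def test_joint_tracers_tighten_cis(self, toy_cycle, toy_cycle_fluxes):
        t1 = TracerSpec("AC.ext", (1, 2), purity=0.99)
        t2 = TracerSpec("Y.ext", (1, 2, 3, 4), purity=0.99)
        e1 = cycle_experiment(toy_cycle, toy_cycle_fluxes, t1)
        e2 = cycle_experiment(toy_cycle, toy_cycle_fluxes, t2)
        single = fit_fluxes(toy_cycle, [e1], n_restarts=2, seed=8)
        joint = fit_fluxes(toy_cycle, [e1, e2], n_restarts=2, seed=8)
        for rid in ("md", "an"):
            ci_s = single.confidence_interval(rid)
            ci_j = joint.confidence_interval(rid)
            assert (ci_j.upper - ci_j.lower) <= (ci_s.upper - ci_s.lower) + 1e-6


class TestReporting:
    def test_summary_and_flux_table(self, cycle_setup):
        net, fluxes, tracer, exp = cycle_setup
        fit = fit_fluxes(net, [exp], n_restarts=2, seed=2)
        text = fit.summary()
        assert "SSR" in text and "net (exchange)" in text
        table = fit.flux_table()
        assert set(table.index) == set(net.reaction_ids)
        assert table.loc["sd", "reversible"]
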