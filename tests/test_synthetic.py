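import numpy as np
import pytest

from adipoflux.isa import isa_fit
from adipoflux.mfa import FluxModel
from adipoflux.synthetic import (
    DEFAULT_ISA_TRUTH,
    MEASUREMENT_PANELS,
    TRACERS,
    generate_isa_dataset,
    generate_medium_timecourse,
    generate_tracer_dataset,
    rates_from_timecourse,
    sample_feasible_fluxes,
)


class TestScenarios:
    def test_control_satisfies_balance(self, reference_network, control_truth):
        control_truth.validate(reference_network)  # raises on violation

    def test_bckdha_ko_ablates_bckdh(self, reference_network, control_truth):
        ko = sample_feasible_fluxes(reference_network, scenario="bckdha_ko")
        ko.validate(reference_network)
        for rid in ("v_bckdh_leu", "v_bckdh_val"):
            assert ko.net[rid] < 0.01 * control_truth.net[rid]

    def test_ko_raises_pyruvate_oxidation_and_carboxylation(self, reference_network, control_truth):
        ko = sample_feasible_fluxes(reference_network, scenario="bckdha_ko")
        assert ko.net["v_pdh"] > control_truth.net["v_pdh"]
        assert ko.net["v_pc"] > control_truth.net["v_pc"]

    @pytest.mark.parametrize("scenario", ["control", "bckdha_ko"])
    def test_oxppp_ratio_held_in_both_scenarios(self, reference_network, scenario):
        fv = sample_feasible_fluxes(reference_network, scenario=scenario)
        assert fv.net["v_ppp"] / fv.net["v_glcup"] == pytest.approx(0.003, rel=1e-9)

    def test_glutamine_fluxes_on_reported_scale(self, control_truth):
        assert control_truth.net["v_glnup"] == pytest.approx(56.0, abs=0.5)
        assert control_truth.net["v_glnsec"] == pytest.approx(43.0, abs=0.5)

    def test_unknown_scenario_rejected(self, reference_network):
        with pytest.raises(ValueError, match="scenario"):
            sample_feasible_fluxes(reference_network, scenario="nope")


class TestTracerDatasets:
    def test_zero_noise_reproduces_simulation(self, reference_network, control_truth):
        exps, truth = generate_tracer_dataset(
            reference_network, control_truth, noise_sd=0.0, n_replicates=1, seed=0,
            rate_rel_sd=0.0,
        )
        for exp, tname in zip(exps, TRACERS):
            for mid in exp.mids:
                np.testing.assert_allclose(
                    mid.fractions, truth["mids"][tname][mid.metabolite], atol=1e-12)
            for rate in exp.rates:
                assert rate.value == pytest.approx(truth["rates"][rate.name])

    def test_same_seed_reproduces_dataset(self, reference_network, control_truth):
        a, _ = generate_tracer_dataset(reference_network, control_truth, seed=5)
        b, _ = generate_tracer_dataset(reference_network, control_truth, seed=5)
        for ea, eb in zip(a, b):
            for ma, mb in zip(ea.mids, eb.mids):
                np.testing.assert_array_equal(ma.fractions, mb.fractions)
            assert [r.value for r in ea.rates] == [r.value for r in eb.rates]

    def test_panels_follow_tracer_reachability(self):
        assert "PYR.c" in MEASUREMENT_PANELS["glucose"]
        assert "PYR.c" not in MEASUREMENT_PANELS["leucine"]
        assert "LEU.c" not in MEASUREMENT_PANELS["valine"]

    def test_noise_magnitude_matches_half_normal_prediction(self, reference_network, control_truth, rng):
        # on channels far from 0 the pre-clip |error| is half-normal with
        # mean sqrt(2/pi) * sd
        from adipoflux.synthetic import _noisy_mid

        mid = np.full(5, 0.2)
        sd = 0.003
        diffs = []
        for _ in range(1000):
            diffs.append(np.abs(_noisy_mid(mid, sd, rng) - mid))
        mean_abs = np.mean(diffs)
        assert mean_abs == pytest.approx(np.sqrt(2 / np.pi) * sd, rel=0.15)

    def test_experiments_fit_interface(self, reference_network, control_truth):
        exps, _ = generate_tracer_dataset(reference_network, control_truth, seed=1)
        model = FluxModel(reference_network, exps)
        assert model.dof > 700
        assert model.ssr_at(control_truth) > 0


class TestIsaDatasets:
    def test_fully_synthesized_fully_enriched_is_all_m16(self):
        mids, _ = generate_isa_dataset({"C16:0": (1.0, 1.0)}, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(mids[0].fractions, np.eye(17)[16], atol=1e-12)

    def test_odd_chain_channel_count(self):
        mids, _ = generate_isa_dataset({"C15:0": (0.3, 0.4)}, noise_sd=0.0, seed=0)
        assert len(mids[0].fractions) == 16  # M0..M15

    def test_round_trip_through_isa_fit(self):
        mids, truth = generate_isa_dataset(seed=3)
        for mid in mids:
            d, g = truth[mid.metabolite]
            res = isa_fit(mid, mid.metabolite)
            dlo, dhi, _ = res.conf_int("D")
            glo, ghi, _ = res.conf_int("g")
            assert dlo - 0.01 <= d <= dhi + 0.01
            assert glo - 0.01 <= g <= ghi + 0.01

    def test_truth_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            generate_isa_dataset({"C16:0": (1.2, 0.5)}, seed=0)


class TestMediumTimecourse:
    def test_zero_rates_leave_medium_unchanged(self):
        df = generate_medium_timecourse({"glucose": 0.0, "lactate": 0.0},
                                        seed=0, rel_noise=0.0)
        np.testing.assert_allclose(df["spent_conc"], df["fresh_conc"])

    def test_exchange_rate_inverts_generator(self):
        df = generate_medium_timecourse({"glucose": 100.0}, seed=1)
        meas = rates_from_timecourse(df)["glucose"]
        # 5% relative noise on the drawdown: 3 sd tolerance
        assert meas.flux == pytest.approx(100.0, abs=3 * 5.0)

    def test_net_of_opposing_glutamine_fluxes(self):
        # uptake 56 with secretion 43 appears in the medium as their difference
        df = generate_medium_timecourse({"glutamine": 56.0 - 43.0}, seed=2,
                                        rel_noise=0.0)
        meas = rates_from_timecourse(df)["glutamine"]
        assert meas.flux == pytest.approx(13.0, abs=1e-9)

    def test_infeasible_drawdown_rejected(self):
        with pytest.raises(ValueError, match="exhausts"):
            generate_medium_timecourse({"glucose": 1e6}, seed=0)
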