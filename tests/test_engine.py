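"""Partitioned survival engine: occupancy, cost accrual, ICER logic."""

import numpy as np
import pytest

from bilicea import (
    CEAResult,
    ModelSettings,
    ParametricFit,
    accrue,
    ae_cost_first_cycle,
    build_trajectory,
    discount_factor,
    drug_cost_cycle,
    run_cea,
    second_line_cost_cycle,
)
from bilicea.config import apply_overrides
from bilicea.engine import ArmResult, StateTrajectory, folfox_cycle_cost
from tests.conftest import analytic_fits

LN2 = np.log(2.0)


def _exp_fit(median):
    return ParametricFit("exponential", (LN2 / median,), loglik=0.0, n_obs=100)


class TestTrajectory:
    def test_partition_rule(self):
        # S_os = 0.8, S_pfs = 0.5 → (0.5, 0.3, 0.2)
        traj = StateTrajectory(np.array([1.0]), np.array([0.5]),
                               np.array([0.3]), np.array([0.2]))
        traj.validate()

    def test_initial_condition_and_conservation(self, settings):
        traj = build_trajectory(_exp_fit(12.7), _exp_fit(6.5), settings)
        assert traj.n_cycles == 174
        assert (traj.pi_pfs[0], traj.pi_pd[0], traj.pi_death[0]) == (1.0, 0.0, 0.0)
        total = traj.pi_pfs + traj.pi_pd + traj.pi_death
        assert np.allclose(total, 1.0, atol=1e-12, rtol=0)
        traj.validate()

    def test_pfs_clamped_to_os(self, settings):
        # PFS curve above OS: occupancy clamps PD to zero
        traj = build_trajectory(_exp_fit(6.0), _exp_fit(12.0), settings)
        assert np.all(traj.pi_pd >= 0)
        assert np.allclose(traj.pi_pd, 0.0)
        assert np.allclose(traj.pi_pfs, 1.0 - traj.pi_death)

    def test_half_cycle_correction_shifts_evaluation(self, settings):
        from dataclasses import replace

        hc = replace(settings, half_cycle_correction=True)
        traj = build_trajectory(_exp_fit(12.7), _exp_fit(6.5), hc)
        assert traj.eval_times[0] == pytest.approx(0.5 * hc.cycle_months)
        assert traj.pi_death[0] > 0


class TestDrugCosts:
    def test_china_cycle_one_hand_arithmetic(self, china):
        # pembrolizumab 2 × 2,517.32; gemcitabine 9 vials × 8.43 × 2;
        # cisplatin 5 vials × 2.42 × 2
        assert drug_cost_cycle("experimental", 1, china) \
            == pytest.approx(5034.64 + 151.74 + 24.20)

    def test_pembrolizumab_stops_after_35_cycles(self, china):
        c35 = drug_cost_cycle("experimental", 35, china)
        c36 = drug_cost_cycle("experimental", 36, china)
        assert c35 - c36 == pytest.approx(5034.64)

    def test_cisplatin_stops_after_8_cycles(self, china):
        c8 = drug_cost_cycle("experimental", 8, china)
        c9 = drug_cost_cycle("experimental", 9, china)
        assert c8 - c9 == pytest.approx(24.20)

    def test_control_arm_has_no_pembrolizumab(self, china):
        assert drug_cost_cycle("control", 1, china) \
            == pytest.approx(151.74 + 24.20)

    def test_cycle_index_is_one_based(self, china):
        with pytest.raises(ValueError):
            drug_cost_cycle("experimental", 0, china)


class TestSecondLine:
    def test_degenerate_mixture_is_bsc(self, china):
        cfg = apply_overrides(china, {"second_line_prop_pem": 0.0,
                                      "io_prop_pem": 0.0})
        assert second_line_cost_cycle("experimental", cfg) \
            == pytest.approx(china.bsc_cost)

    def test_experimental_arm_weights(self, china):
        folfox = folfox_cycle_cost(china)
        io = 2 * 2517.32            # one 200 mg administration, 100 mg vials
        expected = 0.47 * folfox + 0.009 * io + (1 - 0.47 - 0.009) * china.bsc_cost
        assert second_line_cost_cycle("experimental", china) \
            == pytest.approx(expected)

    def test_doubling_folfox_prices_doubles_folfox_component_only(self, china):
        base = second_line_cost_cycle("experimental", china)
        doubled = apply_overrides(china, {
            f"drug_price.{d}": 2 * china.drug_prices[d].usd_per_vial
            for d in ("oxaliplatin", "leucovorin", "fluorouracil")
        })
        new = second_line_cost_cycle("experimental", doubled)
        assert new - base == pytest.approx(0.47 * folfox_cycle_cost(china))


class TestAdverseEvents:
    def test_china_experimental_hand_arithmetic(self, china):
        assert ae_cost_first_cycle("experimental", china) \
            == pytest.approx(0.47 * 354 + 0.12 * 466 + 0.16 * 1814 + 0.24 * 541)

    def test_zero_probabilities_zero_cost(self, china):
        cfg = apply_overrides(china, {f"ae_prob_pem.{ae}": 0.0
                                      for ae in china.ae_prob_pem})
        assert ae_cost_first_cycle("experimental", cfg) == 0.0


class TestDiscounting:
    def test_zero_rate_is_one(self):
        assert all(discount_factor(i, 0.0) == 1.0 for i in range(5))

    def test_one_year_at_five_percent(self):
        cycles_per_year = 365.25 / 21.0
        assert discount_factor(cycles_per_year, 0.05) \
            == pytest.approx(1 / 1.05)

    def test_cycle_zero_is_one(self):
        assert discount_factor(0, 0.12) == 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)


class TestAccrual:
    def test_single_cycle_full_pfs_qaly(self, china, settings):
        traj = StateTrajectory(np.array([0.0]), np.array([1.0]),
                               np.array([0.0]), np.array([0.0]))
        cfg = apply_overrides(china, {"discount_rate": 0.0})
        res = accrue(traj, "experimental", cfg, settings)
        assert res.total_qaly == pytest.approx(0.76 * 21 / 365.25, abs=1e-6)

    def test_utility_one_zero_rate_gives_life_years(self, china, settings):
        fits = analytic_fits(12.7, 6.5)
        traj = build_trajectory(fits["OS"], fits["PFS"], settings)
        cfg = apply_overrides(china, {"u_pfs": 1.0, "u_pd": 1.0,
                                      "discount_rate": 0.0})
        res = accrue(traj, "experimental", cfg, settings)
        ly = settings.cycle_years * np.sum(traj.pi_pfs + traj.pi_pd)
        assert res.total_qaly == pytest.approx(ly, abs=1e-10)

    def test_end_of_life_cost_telescopes(self, china, settings):
        fits = analytic_fits(12.7, 6.5)
        traj = build_trajectory(fits["OS"], fits["PFS"], settings)
        cfg = apply_overrides(china, {"discount_rate": 0.0})
        res = accrue(traj, "experimental", cfg, settings)
        assert res.breakdown["end_of_life"] \
            == pytest.approx(china.eol_cost * traj.pi_death[-1], abs=1e-6)

    def test_zero_rate_matches_undiscounted_oracle_loop(self, china, settings):
        """Independent per-cycle accumulation without vectorization."""
        fits = analytic_fits(12.7, 6.5)
        traj = build_trajectory(fits["OS"], fits["PFS"], settings)
        cfg = apply_overrides(china, {"discount_rate": 0.0})
        res = accrue(traj, "experimental", cfg, settings)

        total = 0.0
        qaly = 0.0
        prev_death = 0.0
        sl = second_line_cost_cycle("experimental", cfg)
        for j in range(traj.n_cycles):
            pfs, pd_, death = traj.pi_pfs[j], traj.pi_pd[j], traj.pi_death[j]
            total += pfs * (drug_cost_cycle("experimental", j + 1, cfg)
                            + cfg.administration_cost)
            total += (pfs + pd_) * cfg.examination_cost
            total += pd_ * sl
            total += (death - prev_death) * cfg.eol_cost
            if j == 0:
                total += ae_cost_first_cycle("experimental", cfg)
            qaly += settings.cycle_years * (cfg.u_pfs * pfs + cfg.u_pd * pd_)
            prev_death = death
        assert res.total_cost == pytest.approx(total, abs=1e-6)
        assert res.total_qaly == pytest.approx(qaly, abs=1e-10)

    def test_breakdown_sums_to_total(self, china, settings):
        fits = analytic_fits(12.7, 6.5)
        traj = build_trajectory(fits["OS"], fits["PFS"], settings)
        res = accrue(traj, "experimental", china, settings)
        res.validate()

    def test_zero_utility_zero_qaly(self, china, settings):
        fits = analytic_fits(12.7, 6.5)
        traj = build_trajectory(fits["OS"], fits["PFS"], settings)
        cfg = apply_overrides(china, {"u_pfs": 0.0, "u_pd": 0.0})
        assert accrue(traj, "experimental", cfg, settings).total_qaly == 0.0

    def test_zero_price_config_leaves_nondrug_components(self, china, settings):
        fits = analytic_fits(12.7, 6.5)
        traj = build_trajectory(fits["OS"], fits["PFS"], settings)
        cfg = apply_overrides(china, {f"drug_price.{d}": 0.0
                                      for d in china.drug_prices})
        res = accrue(traj, "experimental", cfg, settings)
        assert res.breakdown["drug_first_line"] == 0.0
        assert res.breakdown["administration"] > 0
        assert res.breakdown["examination"] > 0

    def test_all_zero_config_gives_zero_totals(self, china, settings):
        fits = analytic_fits(12.7, 6.5)
        traj = build_trajectory(fits["OS"], fits["PFS"], settings)
        zeros = {f"drug_price.{d}": 0.0 for d in china.drug_prices}
        zeros.update({f"ae_cost.{ae}": 0.0 for ae in china.ae_costs})
        zeros.update({
            "examination_cost": 0.0, "administration_cost": 0.0,
            "bsc_cost": 0.0, "eol_cost": 0.0, "u_pfs": 0.0, "u_pd": 0.0,
        })
        cfg = apply_overrides(china, zeros)
        res = accrue(traj, "experimental", cfg, settings)
        assert res.total_cost == 0.0 and res.total_qaly == 0.0


class TestICER:
    @staticmethod
    def _result(dc, dq):
        return CEAResult(
            experimental=ArmResult(total_cost=1000.0 + dc, total_qaly=1.0 + dq,
                                   breakdown={}),
            control=ArmResult(total_cost=1000.0, total_qaly=1.0, breakdown={}),
        )

    def test_simple_ratio(self):
        res = self._result(100.0, 0.5)
        assert res.status == "icer" and res.icer == pytest.approx(200.0)

    def test_dominated(self):
        res = self._result(100.0, -0.5)
        assert res.status == "dominated" and res.icer is None

    def test_dominant(self):
        res = self._result(-100.0, 0.5)
        assert res.status == "dominant" and res.icer is None

    def test_undefined_when_no_qaly_difference(self):
        res = self._result(100.0, 0.0)
        assert res.status == "undefined" and res.icer is None

    def test_savings_per_qaly_lost_is_a_ratio(self):
        res = self._result(-100.0, -0.5)
        assert res.status == "icer" and res.icer == pytest.approx(200.0)


class TestRunCEA:
    def test_identical_arms_undefined(self, china, settings):
        fits = analytic_fits(12.7, 6.5)
        res = run_cea(fits, fits, china, settings)
        assert res.delta_qaly == pytest.approx(0.0, abs=1e-12)
        # experimental arm still pays for pembrolizumab → dearer at equal QALY
        assert res.delta_cost > 0
        assert res.status == "undefined"

    def test_icer_monotone_in_pembrolizumab_price(self, fast_context):
        base_price = fast_context.config.price("pembrolizumab").usd_per_vial
        icers = []
        for scale in (0.5, 1.0, 2.0):
            res = fast_context.run(
                overrides={"drug_price.pembrolizumab": base_price * scale})
            icers.append(res.icer)
        assert icers[0] < icers[1] < icers[2]

    def test_experimental_arm_gains_qalys(self, fast_context):
        res = fast_context.base_result()
        assert res.delta_qaly > 0
        assert res.status == "icer"
        assert res.icer > 0

    def test_missing_endpoint_rejected(self, china, settings):
        fits = analytic_fits(12.7, 6.5)
        with pytest.raises(ValueError, match="PFS"):
            run_cea({"OS": fits["OS"]}, fits, china, settings)
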