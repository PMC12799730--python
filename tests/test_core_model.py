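"""Deterministic model: validation, steady states, calibration, ODE."""

import numpy as np
import pytest

import twocodon as tc
from twocodon.core_model import _solve_flux
from twocodon.gillespie import default_initial_state


class TestModelParams:
    @pytest.mark.parametrize(
        "changes",
        [
            {"T1_tot": -1.0},
            {"R_tot": 0.0},
            {"N": 0.0},
            {"L": 0.5},
            {"k_charge": 0.0},
            {"k_speed": -0.1},
            {"f_op": 1.5},
            {"f_op": -0.1},
        ],
    )
    def test_invalid_fields_rejected(self, baseline, changes):
        with pytest.raises(ValueError):
            baseline.replace(**changes)

    def test_one_species_pool_requires_matching_fop(self, baseline):
        with pytest.raises(ValueError):
            baseline.replace(T2_tot=0.0, f_op=0.5)
        baseline.replace(T2_tot=0.0, f_op=1.0)  # allowed

    def test_preferred_fraction_derived(self, ratio07):
        assert ratio07.preferred_fraction == pytest.approx(0.7)

    def test_dict_round_trip(self, baseline):
        assert tc.ModelParams.from_dict(baseline.to_dict()) == baseline

    def test_unknown_field_rejected(self, baseline):
        d = baseline.to_dict()
        d["banana"] = 1.0
        with pytest.raises(ValueError, match="banana"):
            tc.ModelParams.from_dict(d)


class TestSolveSteadyState:
    def test_baseline_reproduces_calibration_targets(self, baseline):
        """Calibrated baseline: 88% charged, 88% active, density 0.49/100nt."""
        ss = tc.solve_steady_state(baseline)
        summ = tc.summarize(ss, baseline)
        assert summ.charged_frac_total == pytest.approx(0.88, abs=1e-9)
        assert summ.active_ribosome_frac == pytest.approx(0.88, abs=1e-9)
        assert summ.ribosome_density == pytest.approx(0.49, abs=0.005)

    @pytest.mark.parametrize("f_op", [0.01, 0.25, 0.5, 0.77, 0.99])
    @pytest.mark.parametrize("k_charge", [0.5, 3.0, 32.27, 300.0])
    def test_residuals_below_tolerance(self, ratio07, f_op, k_charge):
        p = ratio07.replace(f_op=f_op, k_charge=k_charge)
        ss = tc.solve_steady_state(p)
        assert np.max(tc.residuals(ss, p)) < 1e-10
        assert np.all(ss.as_array() >= 0)
        ss.validate(p)

    def test_fop_zero_leaves_preferred_pool_untouched(self, ratio07):
        """Unused optimal codons: no occupancy, fully charged pool."""
        ss = tc.solve_steady_state(ratio07.replace(f_op=0.0))
        assert ss.R_b1 == 0.0
        assert ss.T_u1 == 0.0
        assert ss.T_c1 == ratio07.T1_tot

    def test_eq13_identity(self, ratio07):
        p = ratio07.replace(f_op=0.3)
        ss = tc.solve_steady_state(p)
        lhs = tc.protein_rate(ss, p) * p.L
        rhs = p.k_speed * (ss.R_b1 * ss.T_c1 + ss.R_b2 * ss.T_c2)
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestClosedFormOneCodon:
    def test_unused_class_idle_and_charged(self, ratio07):
        ss = tc.closed_form_one_codon(ratio07.replace(f_op=1.0))
        assert ss.R_b2 == 0.0 and ss.T_c2 == ratio07.T2_tot

    @pytest.mark.parametrize("f_op", [0.0, 1.0])
    def test_agrees_with_flux_solver(self, baseline, f_op):
        """Independent numerical route reproduces the quadratic root."""
        p = baseline.replace(f_op=f_op)
        cf = tc.closed_form_one_codon(p).as_array()
        fl = _solve_flux(p).as_array()
        np.testing.assert_allclose(cf, fl, rtol=1e-10, atol=1e-10)

    def test_mirror_symmetry_under_species_swap(self, baseline):
        a = tc.closed_form_one_codon(
            baseline.replace(T1_tot=1750, T2_tot=750, f_op=1.0))
        b = tc.closed_form_one_codon(
            baseline.replace(T1_tot=750, T2_tot=1750, f_op=0.0))
        assert a.T_c1 == pytest.approx(b.T_c2, rel=1e-14)
        assert a.R_b1 == pytest.approx(b.R_b2, rel=1e-14)


class TestInfiniteCharging:
    def test_symmetric_pools_make_expression_fop_independent(self, baseline):
        prs = [tc.infinite_charging_limit(baseline.replace(f_op=f))
               for f in (0.0, 0.3, 0.5, 1.0)]
        assert max(prs) == pytest.approx(min(prs), rel=1e-14)

    def test_matches_solver_at_large_k_charge(self, ratio07):
        p = ratio07.replace(k_charge=1e6, f_op=0.6)
        pr = tc.protein_rate(tc.solve_steady_state(p), p)
        assert tc.infinite_charging_limit(p) == pytest.approx(pr, rel=1e-4)

    def test_all_optimal_speed_is_kspeed_T1(self, ratio07):
        p = ratio07.replace(f_op=1.0)
        # per-ribosome speed k_speed*T1_tot => E = speed * R_bound
        pr = tc.infinite_charging_limit(p)
        speed = p.k_speed * p.T1_tot
        rb = pr * p.L / speed
        rf = p.R_tot - rb
        # binding balance closes: kb*N*R_f == P_r
        assert p.k_bind_eff * p.N * rf == pytest.approx(pr, rel=1e-12)


class TestProteinRate:
    def test_no_bound_ribosomes_no_flux(self, baseline):
        ss = default_initial_state(baseline)
        assert tc.protein_rate(ss, baseline) == 0.0

    def test_direct_arithmetic(self, baseline):
        st = tc.SystemState(1100, 1100, 150, 150, 60, 220, 220)
        assert tc.protein_rate(st, baseline) == pytest.approx(
            0.02 * (220 * 1100 + 220 * 1100) / 300
        )
        assert tc.protein_rate(st, baseline) == pytest.approx(32.26667, rel=1e-6)


class TestSummarize:
    def test_active_fraction(self, baseline):
        st = tc.SystemState(1100, 1100, 150, 150, 60, 220, 220)
        assert tc.summarize(st, baseline).active_ribosome_frac == pytest.approx(0.88)

    def test_ribosome_density_per_100nt(self, baseline):
        st = tc.SystemState(1100, 1100, 150, 150, 60, 220, 220)
        dens = tc.summarize(st, baseline).ribosome_density
        assert dens == pytest.approx(100 * 440 / (100 * 300 * 3))
        assert round(dens, 2) == 0.49

    def test_fully_charged_pool(self, baseline):
        st = default_initial_state(baseline)
        assert tc.summarize(st, baseline).charged_frac_total == 1.0
        assert tc.summarize(st, baseline).per_ribosome_speed == 0.0


class TestCalibrate:
    def test_reproduces_stored_reference_constants(self, baseline):
        kc, kb = tc.calibrate(baseline, 0.88, 0.88)
        assert kc == pytest.approx(baseline.k_charge, rel=1e-14)
        assert kb == pytest.approx(baseline.k_bind_eff, rel=1e-14)

    @pytest.mark.parametrize("targets", [(0.7, 0.5), (0.95, 0.9), (0.6, 0.97)])
    def test_round_trip(self, ratio07, targets):
        c, a = targets
        kc, kb = tc.calibrate(ratio07, c, a)
        p = ratio07.replace(k_charge=kc, k_bind_eff=kb)
        summ = tc.summarize(tc.solve_steady_state(p), p)
        assert summ.charged_frac_total == pytest.approx(c, abs=1e-6)
        assert summ.active_ribosome_frac == pytest.approx(a, abs=1e-6)

    def test_full_activity_infeasible(self, baseline):
        with pytest.raises(tc.CalibrationError):
            tc.calibrate(baseline, 0.88, 1.0)

    def test_draining_charged_fraction_infeasible(self, baseline):
        # at f_op=0.9 a charged fraction of 0.2 would require T_c1 < 0
        with pytest.raises(tc.CalibrationError, match="achievable"):
            tc.calibrate(baseline.replace(f_op=0.9), 0.2, 0.5)


class TestMolarConversion:
    def test_unit_volume_product(self):
        assert tc.molar_to_effective_bind(2.5e6, 2.5e6 / tc.AVOGADRO) == pytest.approx(1.0)

    def test_ecoli_like_volume(self):
        # 2.5e6 / (6.02214076e23 * 8e-16) — direct arithmetic
        assert tc.molar_to_effective_bind(2.5e6, 8e-16) == pytest.approx(
            5.18918e-3, rel=1e-5
        )

    def test_inverse_proportional_to_volume(self):
        assert tc.molar_to_effective_bind(1e6, 2e-15) == pytest.approx(
            tc.molar_to_effective_bind(1e6, 1e-15) / 2
        )

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            tc.molar_to_effective_bind(0.0, 1e-15)


class TestOdeRhs:
    def test_zero_at_fixed_point(self, ratio07):
        p = ratio07.replace(f_op=0.42, k_charge=5.0)
        ss = tc.solve_steady_state(p)
        assert np.max(np.abs(tc.ode_rhs(ss, p))) < 1e-8

    def test_conservation_of_derivatives_anywhere(self, baseline):
        st = tc.SystemState(900, 1000, 350, 250, 100, 150, 250)
        d = tc.ode_rhs(st, baseline)
        assert d[0] + d[2] == pytest.approx(0.0, abs=1e-12)  # tRNA species 1
        assert d[1] + d[3] == pytest.approx(0.0, abs=1e-12)  # tRNA species 2
        assert d[4] + d[5] + d[6] == pytest.approx(0.0, abs=1e-12)  # ribosomes


class TestIntegrateTimecourse:
    def test_time_zero_returns_init(self, baseline):
        init = default_initial_state(baseline)
        tr = tc.integrate_timecourse(baseline, init, [0.0])
        np.testing.assert_array_equal(tr.states[0], init.as_array())

    def test_steady_init_stays_constant(self, baseline):
        ss = tc.solve_steady_state(baseline)
        tr = tc.integrate_timecourse(baseline, ss, np.linspace(0, 500, 6))
        for row in tr.states:
            np.testing.assert_allclose(row, ss.as_array(), rtol=1e-6)

    def test_relaxes_to_fixed_point(self, baseline):
        """All-charged/all-free start converges to the solver's fixed point."""
        init = default_initial_state(baseline)
        tr = tc.integrate_timecourse(baseline, init, [0.0, 10_000.0])
        ss = tc.solve_steady_state(baseline).as_array()
        np.testing.assert_allclose(tr.states[-1], ss, rtol=1e-6)

    def test_conservation_along_trajectory(self, ratio09):
        init = default_initial_state(ratio09)
        tr = tc.integrate_timecourse(ratio09, init, np.linspace(0, 2000, 21))
        tot = ratio09.T1_tot + ratio09.T2_tot
        np.testing.assert_allclose(
            tr.states[:, 0] + tr.states[:, 2], ratio09.T1_tot, rtol=1e-8)
        np.testing.assert_allclose(
            tr.states[:, 4:7].sum(axis=1), ratio09.R_tot, rtol=1e-8)
        assert np.all(np.diff(tr.protein) >= 0)

    def test_rejects_inconsistent_init(self, baseline):
        bad = tc.SystemState(1250, 1250, 0, 0, 400, 0, 0)  # ribosomes missing
        with pytest.raises(ValueError):
            tc.integrate_timecourse(baseline, bad, [0.0, 1.0])
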