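"""Whole-body PBPK engine: conservation, linear-systems oracle, kinetics."""

import numpy as np
import pytest
from scipy.linalg import expm

from ivmpbpk import build_model, build_individual, pk_metrics, simulate
from ivmpbpk.engine import IDX_VEN, SPLANCHNIC, TISSUES
from ivmpbpk.nca import auc_lin_up_log_down
from ivmpbpk.trials import DEFAULT_SAMPLING, replace_compound


def systemic_matrix(system):
    """Independent construction of the linear disposition system (IV only):
    14 tissue states + venous + arterial, lung in series, splanchnic organs
    draining to the liver, well-stirred hepatic elimination."""
    n = len(TISSUES) + 2
    i_ven, i_art = n - 2, n - 1
    A = np.zeros((n, n))
    q, v, kp = system.q_tissue, system.v_tissue, system.kp
    bp, co = system.bp, system.cardiac_output
    clint = system.cl_int_met + system.cl_int_bil
    i_li = TISSUES.index("liver")
    i_lu = TISSUES.index("lung")
    spl = [TISSUES.index(t) for t in SPLANCHNIC]
    q_ha = q[i_li] - sum(q[s] for s in spl)
    for i in range(len(TISSUES)):
        cv_coef = bp / (v[i] * kp[i])
        if i == i_lu:
            A[i, i_ven] += co / system.v_ven
            A[i, i] -= co * cv_coef
            A[i_art, i] += co * cv_coef
        elif i == i_li:
            A[i, i_art] += q_ha / system.v_art
            for s in spl:
                A[i, s] += q[s] * bp / (v[s] * kp[s])
            A[i, i] -= (q[i] + system.fu_blood * clint) * cv_coef
            A[i_ven, i] += q[i] * cv_coef
        elif i in spl:
            A[i, i_art] += q[i] / system.v_art
            A[i, i] -= q[i] * cv_coef
        else:
            A[i, i_art] += q[i] / system.v_art
            A[i, i] -= q[i] * cv_coef
            A[i_ven, i] += q[i] * cv_coef
    A[i_ven, i_ven] -= co / system.v_ven
    A[i_art, i_art] -= co / system.v_art
    return A


class TestStructure:
    def test_flow_network_sums_to_cardiac_output(self, ivermectin, ref_adult):
        from dataclasses import replace

        system = build_model(ref_adult, ivermectin)  # audited at construction
        q_lung = system.q_tissue[TISSUES.index("lung")]
        q_liver = system.q_tissue[TISSUES.index("liver")]
        q_spl = sum(system.q_tissue[TISSUES.index(t)] for t in SPLANCHNIC)
        arterial = system.q_tissue.sum() - q_lung - q_liver + (q_liver - q_spl)
        assert arterial == pytest.approx(ref_adult.cardiac_output, rel=1e-9)
        bad_q = system.q_tissue.copy()
        bad_q[0] *= 1.5
        with pytest.raises(ValueError, match="flow network"):
            replace(system, q_tissue=bad_q)

    def test_zero_dose_gives_identically_zero_states(self, ivermectin, ref_adult):
        profile = simulate(build_model(ref_adult, ivermectin), 0.0, t_end=12.0)
        assert np.all(profile.amounts == 0.0)
        assert np.all(profile.plasma_conc == 0.0)


class TestClosedFormOracles:
    def test_iv_bolus_matches_matrix_exponential(self, ivermectin, ref_adult):
        """The disposition sub-system is linear; an IV bolus profile must
        match the matrix-exponential solution of an independently built
        system matrix (the multi-compartment generalization of the
        bi-exponential two-compartment solution)."""
        system = build_model(ref_adult, ivermectin)
        A = systemic_matrix(system)
        y0 = np.zeros(A.shape[0])
        y0[IDX_VEN - 28] = 1.0  # venous index within the systemic block
        times = np.array([0.5, 2.0, 8.0, 24.0, 48.0])
        profile = simulate(system, 0.0, t_end=48.0, output_grid=times,
                           iv_bolus_mg=1.0, rtol=1e-10, atol=1e-13)
        for k, t in enumerate(times):
            y = expm(A * t) @ y0
            expected = y[len(TISSUES)] / system.v_ven / system.bp * 1000.0
            assert profile.plasma_conc[k] == pytest.approx(expected, rel=1e-6)

    def test_constant_infusion_steady_state(self, ivermectin, ref_adult):
        """Css from a constant-rate infusion with hepatic-only elimination
        equals the closed-form arterial R/CL_b minus the venous CO offset."""
        from ivmpbpk.disposition import well_stirred_hepatic_cl

        system = build_model(ref_adult, ivermectin)
        rate = 1.0  # mg/h
        clint = system.cl_int_met + system.cl_int_bil
        cl_b, _ = well_stirred_hepatic_cl(clint, system.fu_blood, system.q_tissue[TISSUES.index("liver")])
        # venous infusion at steady state: venous == arterial == R / CL_b
        expected_plasma = rate / cl_b / system.bp * 1000.0
        profile = simulate(system, 0.0, t_end=3000.0,
                           output_grid=np.array([2500.0, 3000.0]),
                           infusion_mg_per_h=rate)
        assert profile.plasma_conc[-1] == pytest.approx(expected_plasma, rel=5e-3)


class TestConservationAndLinearity:
    def test_oral_mass_balance(self, reference_profile_12mg):
        assert reference_profile_12mg.mass_balance_error() < 1e-6

    def test_low_dose_linearity(self, ivermectin, ref_adult):
        cpd = replace_compound(ivermectin, s_aq_intrinsic=50.0, km_w_unionized=0.0,
                               particle_radius=2.0)
        system = build_model(ref_adult, cpd)
        p1 = simulate(system, 1.0)
        p2 = simulate(system, 2.0)
        m1 = pk_metrics(p1, DEFAULT_SAMPLING)
        m2 = pk_metrics(p2, DEFAULT_SAMPLING)
        assert m2.cmax == pytest.approx(2 * m1.cmax, rel=1e-3)
        assert m2.auc_0_t == pytest.approx(2 * m1.auc_0_t, rel=1e-3)

    def test_output_grid_independence_of_auc(self, ivermectin, ref_adult):
        system = build_model(ref_adult, ivermectin)
        auc = {}
        for dt in (0.25, 0.125):
            p = simulate(system, 12.0, output_grid=np.arange(0.0, 72.0 + 1e-9, dt))
            auc[dt] = auc_lin_up_log_down(p.times, p.plasma_conc)
        assert abs(auc[0.25] - auc[0.125]) / auc[0.125] < 0.002


class TestDisposition:
    def test_tmax_near_four_hours_at_12mg(self, reference_profile_12mg):
        m = pk_metrics(reference_profile_12mg, DEFAULT_SAMPLING)
        assert 3.0 <= m.tmax <= 5.0

    def test_half_life_increases_with_adipose_volume(self, ivermectin):
        """Heavier-for-height subjects carry more adipose; with adipose the
        deepest compartment, the apparent terminal half-life lengthens."""
        t_halves = []
        for weight in (60.0, 80.0, 100.0):
            subj = build_individual(30.0, "male", weight, 176.0)
            profile = simulate(build_model(subj, ivermectin), 12.0)
            t_halves.append(pk_metrics(profile, DEFAULT_SAMPLING).t_half)
        assert t_halves[0] < t_halves[1] < t_halves[2]
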