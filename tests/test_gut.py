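"""Luminal transit/dissolution/absorption model: oracles and invariants."""

from dataclasses import replace

import numpy as np
import pytest

from ivmpbpk import (
    GutPhysiology,
    dissolution_rate,
    predict_peff,
    segment_solubility,
    simulate_gut,
)
from ivmpbpk.gut import absorption_rate_constants
from ivmpbpk.trials import replace_compound


class TestSegmentSolubility:
    def test_below_cmc_returns_aqueous_exactly(self, ivermectin):
        cpd = replace_compound(ivermectin, km_w_unionized=1e6)
        s = segment_solubility(cpd, 6.5, bile_salt_conc=0.4, cmc=0.5)
        assert s == cpd.s_aq_intrinsic

    def test_no_micelles_neutral_is_ph_independent(self, ivermectin):
        cpd = replace_compound(ivermectin, km_w_unionized=0.0)
        vals = [segment_solubility(cpd, ph, 15.0) for ph in (1.5, 5.0, 6.5, 7.4)]
        assert all(v == cpd.s_aq_intrinsic for v in vals)

    def test_fassif_conditions_reproduce_measured_value(self, ivermectin):
        s = segment_solubility(ivermectin, 6.5, 3.0, cmc=0.0)
        assert s == pytest.approx(0.12, rel=1e-3)

    def test_monoprotic_acid_henderson_hasselbalch(self, ivermectin):
        acid = replace_compound(
            ivermectin, name="synthetic_acid", ionization_class="monoprotic_acid",
            pka=[5.0], km_w_unionized=0.0,
        )
        s = segment_solubility(acid, 6.5, 0.0)
        assert s == pytest.approx(acid.s_aq_intrinsic * (1 + 10 ** 1.5), rel=1e-9)


class TestDissolutionRate:
    def test_saturated_solution_stops_dissolution(self, ivermectin):
        assert dissolution_rate(ivermectin, 5.0, 0.12, 0.12, 10.0) == 0.0

    def test_no_solid_no_rate(self, ivermectin):
        assert dissolution_rate(ivermectin, 0.0, 0.0, 0.12, 10.0) == 0.0

    def test_linear_in_driving_force(self, ivermectin):
        r1 = dissolution_rate(ivermectin, 5.0, 0.0, 0.06, 10.0)
        r2 = dissolution_rate(ivermectin, 5.0, 0.0, 0.12, 10.0)
        assert r2 == pytest.approx(2 * r1, rel=1e-9)

    def test_negative_mass_rejected(self, ivermectin):
        with pytest.raises(ValueError):
            dissolution_rate(ivermectin, -1.0, 0.0, 0.12, 10.0)


class TestPeff:
    def test_caco2_single_point_calibration(self, ivermectin):
        assert predict_peff(ivermectin) == pytest.approx(2.9 * 190.0 / 62.1, rel=1e-9)

    def test_identity_when_equal_to_control(self, ivermectin):
        cpd = replace_compound(ivermectin, papp_caco2=62.1)
        assert predict_peff(cpd) == pytest.approx(2.9)

    def test_absorption_constant_inverse_in_radius(self, ivermectin, fasted_gut):
        halved = replace(fasted_gut, radii_cm=fasted_gut.radii_cm / 2.0)
        ka = absorption_rate_constants(ivermectin, fasted_gut)
        ka_halved = absorption_rate_constants(ivermectin, halved)
        assert np.allclose(ka_halved, 2.0 * ka)


class TestSimulateGut:
    @pytest.mark.parametrize("dose", [2.6, 12.0, 120.0])
    def test_mass_balance(self, ivermectin, fasted_gut, dose):
        res = simulate_gut(ivermectin, fasted_gut, dose)
        assert res.mass_balance_error() < 1e-6

    def test_fa_non_increasing_in_dose(self, ivermectin, fasted_gut):
        fas = [simulate_gut(ivermectin, fasted_gut, d).fa for d in (3.0, 12.0, 48.0)]
        assert fas[0] > fas[1] > fas[2]

    def test_fa_non_decreasing_in_bile_salts(self, ivermectin, fasted_gut):
        fas = [
            simulate_gut(ivermectin, fasted_gut.scaled(1.0, bile_scalar=b), 30.0).fa
            for b in (0.5, 1.0, 2.0)
        ]
        assert fas[0] < fas[1] < fas[2]

    def test_fa_non_decreasing_in_aqueous_solubility(self, ivermectin, fasted_gut):
        fas = [
            simulate_gut(
                replace_compound(ivermectin, s_aq_intrinsic=s), fasted_gut, 30.0
            ).fa
            for s in (0.00035, 0.0007, 0.0014)
        ]
        assert fas[0] < fas[1] < fas[2]

    def test_fa_non_decreasing_in_permeability(self, ivermectin, fasted_gut):
        fas = [
            simulate_gut(replace_compound(ivermectin, papp_caco2=p), fasted_gut, 30.0).fa
            for p in (95.0, 190.0, 380.0)
        ]
        assert fas[0] < fas[1] < fas[2]

    def test_fed_at_least_fasted(self, ivermectin, fasted_gut, fed_gut):
        for dose in (12.0, 60.0):
            assert (
                simulate_gut(ivermectin, fed_gut, dose).fa
                >= simulate_gut(ivermectin, fasted_gut, dose).fa
            )

    def test_unlimited_solubility_and_permeability_absorb_everything(self, ivermectin, fasted_gut):
        cpd = replace_compound(
            ivermectin, s_aq_intrinsic=100.0, particle_radius=1.0, papp_caco2=1900.0
        )
        assert simulate_gut(cpd, fasted_gut, 120.0).fa > 0.995

    def test_rejects_non_positive_dose(self, ivermectin, fasted_gut):
        with pytest.raises(ValueError):
            simulate_gut(ivermectin, fasted_gut, 0.0)

    def test_trajectory_frame_is_tidy(self, ivermectin, fasted_gut):
        df = simulate_gut(ivermectin, fasted_gut, 12.0, n_out=21).to_frame()
        assert set(df.columns) == {
            "time_h", "segment", "undissolved_mg", "dissolved_mg", "absorbed_mg"
        }
        assert df.segment.nunique() == 9


class TestSingleSegmentOracle:
    """Low-dose limit against the closed-form 1 - exp(-ka * tau) solution.

    The cascade is reduced to one absorbing segment (jejunum-1): everything
    upstream transits instantaneously, everything downstream does not absorb,
    and the compound dissolves freely, so the fraction absorbed is governed
    by first-order absorption during a single mean residence time. fa is also
    dose-independent in this solubility-unlimited limit.
    """

    def _one_segment_gut(self, tau: float):
        g = GutPhysiology.fasted_adult()
        scalars = np.zeros(9)
        scalars[2] = 1.0  # jejunum-1 only
        fast = tau / 50.0  # upstream/downstream segments pass through quickly
        transit = np.array([fast, fast, tau, fast, fast, fast, fast, fast, 5 * fast])
        return replace(g, absorption_scalar=scalars, transit_time_h=transit)

    def _free_compound(self, ivermectin):
        # dissolves within milliseconds and never approaches saturation
        return replace_compound(
            ivermectin, s_aq_intrinsic=5.0, km_w_unionized=0.0, particle_radius=1.5
        )

    def test_matches_analytic_within_5_percent(self, ivermectin):
        tau = 0.02  # short residence: well-mixed and plug-flow limits agree
        gut = self._one_segment_gut(tau)
        cpd = self._free_compound(ivermectin)
        ka = absorption_rate_constants(cpd, gut)[2]
        expected_cstr = ka / (ka + 1.0 / tau)  # exact for the well-mixed segment
        expected_pfr = 1.0 - np.exp(-ka * tau)
        fa = simulate_gut(cpd, gut, 0.01, t_end=0.5, rtol=1e-9).fa
        assert fa == pytest.approx(expected_cstr, rel=5e-3)
        assert abs(fa - expected_pfr) / expected_pfr < 0.05

    def test_low_dose_fa_is_dose_independent(self, ivermectin):
        gut = self._one_segment_gut(1.0)
        cpd = self._free_compound(ivermectin)
        fa1 = simulate_gut(cpd, gut, 0.001, t_end=3.0).fa
        fa2 = simulate_gut(cpd, gut, 0.01, t_end=3.0).fa
        assert fa1 == pytest.approx(fa2, rel=1e-3)
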