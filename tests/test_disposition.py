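"""Tissue partitioning, Vss, and clearance allocation."""

import numpy as np
import pytest

from ivmpbpk import (
    TissueComposition,
    allocate_clearance,
    build_model,
    compute_vss,
    load_tissue_compositions,
    predict_kp,
    predict_kp_set,
    simulate,
)
from ivmpbpk.disposition import well_stirred_hepatic_cl
from ivmpbpk.nca import auc_lin_up_log_down
from ivmpbpk.trials import replace_compound


def kp_oracle(compound, tissue):
    """Independent re-implementation of the tissue-composition Kp equation
    (neutral-species lipid partitioning, pH-partitioned water spaces,
    vegetable-oil coefficient for adipose), written without reference to the
    production code path."""
    import math

    p = math.pow(10.0, compound.log_p)
    p_nl = math.pow(10.0, 1.115 * compound.log_p - 1.34) if tissue.name == "adipose" else p
    if compound.ionization_class == "neutral":
        fn_p = fn_iw = 1.0
    else:
        sign = +1 if compound.ionization_class == "monoprotic_acid" else -1
        fn_p = 1.0 / (1.0 + math.pow(10.0, sign * (7.4 - compound.pka[0])))
        fn_iw = 1.0 / (1.0 + math.pow(10.0, sign * (7.0 - compound.pka[0])))
    kpu = tissue.f_ew
    kpu += tissue.f_iw * fn_p / fn_iw
    kpu += fn_p * (p_nl * tissue.f_nl + (0.3 * p + 0.7) * tissue.f_npl)
    return compound.fu_plasma * compound.kp_scalar * kpu


class TestPredictKp:
    def test_water_only_tissue_with_no_lipophilicity_gives_unity(self, ivermectin):
        water = TissueComposition("water", 0.5, 0.5, 0.0, 0.0)
        cpd = replace_compound(ivermectin, log_p=-10.0, fu_plasma=1.0, kp_scalar=1.0)
        assert predict_kp(cpd, water) == pytest.approx(1.0, rel=1e-6)

    def test_matches_independent_oracle_on_tissue_by_compound_grid(self, ivermectin):
        tissues = load_tissue_compositions()
        compounds = [
            replace_compound(ivermectin, name="n1", log_p=2.0, fu_plasma=0.5, kp_scalar=1.0),
            replace_compound(ivermectin, name="n2", log_p=4.5, fu_plasma=0.05, kp_scalar=0.3),
            replace_compound(ivermectin, name="n3", log_p=0.5, fu_plasma=1.0, kp_scalar=1.0),
            replace_compound(
                ivermectin, name="acid", ionization_class="monoprotic_acid",
                pka=[4.2], log_p=2.5, fu_plasma=0.2, kp_scalar=1.0,
            ),
            replace_compound(
                ivermectin, name="base", ionization_class="monoprotic_base",
                pka=[6.0], log_p=3.0, fu_plasma=0.3, kp_scalar=1.0,
            ),
        ]
        for cpd in compounds:
            for tissue in tissues.values():
                expected = kp_oracle(cpd, tissue)
                assert predict_kp(cpd, tissue) == pytest.approx(expected, rel=1e-4)

    def test_adipose_kp_increases_with_log_p(self, ivermectin):
        adipose = load_tissue_compositions()["adipose"]
        kps = [
            predict_kp(replace_compound(ivermectin, log_p=lp), adipose)
            for lp in (3.5, 4.0, 4.5, 5.0)
        ]
        assert np.all(np.diff(kps) > 0)

    def test_strong_base_unsupported(self, ivermectin):
        base = replace_compound(
            ivermectin, name="strong_base", ionization_class="monoprotic_base", pka=[9.0]
        )
        with pytest.raises(ValueError, match="base"):
            predict_kp(base, load_tissue_compositions()["muscle"])


class TestVss:
    def test_unit_partitioning_recovers_total_volume(self):
        vols = {"a": 20.0, "b": 19.0}
        # B:P equal to the plasma fraction makes the red-cell term vanish
        vss = compute_vss({"a": 1.0, "b": 1.0}, vols, plasma_volume_l=3.0,
                          blood_to_plasma=0.55, hematocrit=0.45)
        assert vss == pytest.approx(42.0)

    def test_hand_worked_three_tissue_example(self):
        kp = {"x": 2.0, "y": 0.5, "z": 10.0}
        vols = {"x": 1.0, "y": 2.0, "z": 3.0}
        vss = compute_vss(kp, vols, plasma_volume_l=3.0, blood_to_plasma=0.55,
                          hematocrit=0.45)
        assert vss == pytest.approx(3.0 + 2.0 + 1.0 + 30.0)

    def test_merging_tissues_with_equal_kp_preserves_vss(self):
        kp = {"x": 2.5, "y": 2.5, "z": 1.0}
        vols = {"x": 4.0, "y": 6.0, "z": 2.0}
        merged = compute_vss({"xy": 2.5, "z": 1.0}, {"xy": 10.0, "z": 2.0}, 3.0, 0.55, 0.45)
        assert compute_vss(kp, vols, 3.0, 0.55, 0.45) == pytest.approx(merged)

    def test_higher_adipose_volume_raises_vss(self, ivermectin, ref_adult):
        kp = predict_kp_set(ivermectin)
        vols = dict(ref_adult.tissue_volumes)
        base = compute_vss(kp, vols, ref_adult.plasma_volume,
                           ivermectin.blood_to_plasma, ref_adult.hematocrit)
        vols["adipose"] += 10.0
        assert compute_vss(kp, vols, ref_adult.plasma_volume,
                           ivermectin.blood_to_plasma, ref_adult.hematocrit) > base

    def test_missing_tissue_raises(self):
        with pytest.raises(KeyError):
            compute_vss({"x": 1.0}, {"x": 1.0, "y": 2.0}, 3.0)


class TestAllocateClearance:
    def test_well_stirred_bounds(self):
        cl, fh = well_stirred_hepatic_cl(1e6, 0.1, 90.0)
        assert cl < 90.0 and 0.0 < fh < 1.0

    def test_zero_intrinsic_clearance_limit(self):
        cl, fh = well_stirred_hepatic_cl(0.0, 0.1, 90.0)
        assert cl == 0.0 and fh == 1.0

    def test_split_preserves_fm_cyp3a4(self, ivermectin, ref_adult):
        alloc = allocate_clearance(15.0, 0.55, ivermectin, ref_adult.liver_blood_flow)
        total = alloc.cl_int_met + alloc.cl_int_bil
        assert alloc.cl_int_met / total == pytest.approx(0.08)
        assert alloc.cl_int_bil / total >= 0.92 - 1e-12

    def test_infeasible_target_rejected(self, ivermectin, ref_adult):
        with pytest.raises(ValueError, match="liver blood flow"):
            allocate_clearance(1e6, 1.0, ivermectin, ref_adult.liver_blood_flow)

    def test_invalid_fa_rejected(self, ivermectin, ref_adult):
        with pytest.raises(ValueError):
            allocate_clearance(15.0, 0.0, ivermectin, ref_adult.liver_blood_flow)

    def test_forward_inverse_reproduces_oral_clearance(self, ivermectin, ref_adult):
        """Allocate from a CL/F target, run the full oral model to completion,
        and recover AUC = dose / (CL/F) within 1% (closed-form identity)."""
        target_cl_over_f = 15.0  # L/h
        dose = 1.0  # mg, low enough for solubility-unlimited absorption
        cpd = replace_compound(
            ivermectin, s_aq_intrinsic=50.0, particle_radius=2.0, km_w_unionized=0.0
        )
        system = build_model(ref_adult, cpd)
        profile = simulate(system, dose, t_end=400.0,
                           output_grid=np.arange(0.0, 400.1, 0.5))
        fa = profile.fa
        alloc = allocate_clearance(target_cl_over_f, fa, cpd, ref_adult.liver_blood_flow)
        cpd2 = replace_compound(
            cpd,
            cl_int_met=alloc.cl_int_met / ref_adult.cyp3a4_rel,
            cl_biliary=alloc.cl_int_bil / ref_adult.cl_bil_scalar,
        )
        profile2 = simulate(build_model(ref_adult, cpd2), dose, t_end=400.0,
                            output_grid=np.arange(0.0, 400.1, 0.5))
        auc = auc_lin_up_log_down(profile2.times, profile2.plasma_conc) / 1000.0
        expected_auc = dose / target_cl_over_f  # mg*h/L
        assert auc == pytest.approx(expected_auc, rel=0.01)
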