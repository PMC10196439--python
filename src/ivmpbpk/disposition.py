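"""Tissue partitioning and systemic clearance allocation.

Tissue:plasma partition coefficients (Kp) follow the tissue-composition
approach of Rodgers and Rowland: unbound drug equilibrates across tissue
water, the neutral species partitions into neutral lipid (P-weighted) and
neutral phospholipid (0.3 P + 0.7), and for ionizable compounds the water
terms carry Henderson-Hasselbalch factors for the intracellular/plasma pH
difference.  A single global ``kp_scalar`` (calibrated against the observed
terminal half-life) multiplies all predicted Kp values.

Systemic clearance is hepatic only (biliary excretion dominant, a minor
CYP3A4-mediated metabolic component, no renal excretion) under the
well-stirred liver model, and is back-calculated ("retrograde") from the
oral-clearance scale observed clinically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .compound import CompoundParameters

if TYPE_CHECKING:  # pragma: no cover
    from .population import IndividualPhysiology

PH_INTRACELLULAR = 7.0
PH_PLASMA = 7.4

#: tissues whose neutral-lipid partitioning uses the vegetable-oil:water
#: coefficient (log Dvo:w = 1.115 logP - 1.34) instead of octanol:water
ADIPOSE_LIKE = ("adipose",)


@dataclass(frozen=True)
class TissueComposition:
    """Fractional tissue composition (unitless volume fractions)."""

    name: str
    f_ew: float  # extracellular water
    f_iw: float  # intracellular water
    f_nl: float  # neutral lipid
    f_npl: float  # neutral phospholipid
    ap_mg_per_g: float = 0.0  # acidic phospholipid (stored; unused for neutrals)

    def __post_init__(self) -> None:
        for f in (self.f_ew, self.f_iw, self.f_nl, self.f_npl):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.name}: composition fractions must be in [0,1]")
        if self.f_ew + self.f_iw + self.f_nl + self.f_npl > 1.0:
            raise ValueError(f"{self.name}: water + lipid fractions exceed 1")


def load_tissue_compositions(path: str | Path | None = None) -> dict[str, TissueComposition]:
    """Load the versioned tissue-composition table shipped with the package."""
    p = Path(path) if path else Path(__file__).parent / "data" / "tissue_composition.csv"
    df = pd.read_csv(p)
    return {
        r.tissue: TissueComposition(
            r.tissue, r.f_ew, r.f_iw, r.f_nl, r.f_npl, r.ap_mg_per_g
        )
        for r in df.itertuples()
    }


def predict_kp(compound: CompoundParameters, tissue: TissueComposition) -> float:
    """Tissue:plasma partition coefficient for a perfusion-limited tissue.

    Neutral species partition into lipids; water spaces see total (neutral +
    ionized) drug with the intracellular pH shift.  Kp = fu * Kpu * kp_scalar
    where Kpu is the tissue:plasma-water ratio.  For adipose the neutral-lipid
    partition coefficient is the vegetable-oil:water value predicted from
    log P (log Dvo:w = 1.115 log P - 1.34), the standard correction without
    which octanol overstates triglyceride partitioning of very lipophilic
    compounds.  Strong bases (pKa > 7), whose tissue binding is dominated by
    acidic phospholipids, are not supported.
    """
    if compound.ionization_class == "monoprotic_base" and compound.pka and compound.pka[0] > PH_INTRACELLULAR:
        raise ValueError(
            "unsupported ionization class: moderate-to-strong base requires "
            "acidic-phospholipid binding terms not implemented here"
        )
    p_ow = 10.0 ** compound.log_p
    p_nl = (
        10.0 ** (1.115 * compound.log_p - 1.34)
        if tissue.name in ADIPOSE_LIKE
        else p_ow
    )
    fn_plasma = compound.neutral_fraction(PH_PLASMA)
    fn_iw = compound.neutral_fraction(PH_INTRACELLULAR)
    kpu = (
        tissue.f_ew
        + tissue.f_iw * fn_plasma / fn_iw
        + fn_plasma * (p_nl * tissue.f_nl + (0.3 * p_ow + 0.7) * tissue.f_npl)
    )
    return compound.fu_plasma * kpu * compound.kp_scalar


def predict_kp_set(
    compound: CompoundParameters,
    compositions: dict[str, TissueComposition] | None = None,
) -> dict[str, float]:
    comps = compositions if compositions is not None else load_tissue_compositions()
    return {name: predict_kp(compound, tc) for name, tc in comps.items()}


def compute_vss(
    kp_set: dict[str, float],
    tissue_volumes_l: dict[str, float],
    plasma_volume_l: float,
    blood_to_plasma: float = 1.0,
    hematocrit: float = 0.45,
) -> float:
    """Steady-state volume of distribution, L (plasma reference).

    Vss = Vp + Ve*E:P + sum_t Kp_t * V_t, with the red-cell term folded in
    through the blood:plasma ratio: E:P = (B:P - (1 - Hct))/Hct.
    """
    missing = [t for t in tissue_volumes_l if t not in kp_set]
    if missing:
        raise KeyError(f"missing Kp for tissues: {missing}")
    v_cells = plasma_volume_l * hematocrit / (1.0 - hematocrit)
    ep_ratio = max(0.0, (blood_to_plasma - (1.0 - hematocrit)) / hematocrit)
    vss = plasma_volume_l + v_cells * ep_ratio
    for t, v in tissue_volumes_l.items():
        vss += kp_set[t] * v
    return vss


@dataclass(frozen=True)
class ClearanceAllocation:
    """Split of systemic clearance between routes, reference-adult scale.

    ``cl_int_met`` and ``cl_int_bil`` are unbound intrinsic clearances (L/h);
    ``cl_hepatic_blood`` is the emergent well-stirred hepatic blood clearance.
    """

    cl_int_met: float
    cl_int_bil: float
    cl_hepatic_blood: float
    fm_cyp3a4: float
    fh: float
    cl_renal: float = 0.0

    def __post_init__(self) -> None:
        if min(self.cl_int_met, self.cl_int_bil, self.cl_renal) < 0:
            raise ValueError("clearance terms must be non-negative")


def well_stirred_hepatic_cl(
    cl_int_unbound: float, fu_blood: float, q_liver_blood: float
) -> tuple[float, float]:
    """Hepatic blood clearance and Fh under the well-stirred liver model."""
    cl = q_liver_blood * fu_blood * cl_int_unbound / (q_liver_blood + fu_blood * cl_int_unbound)
    fh = q_liver_blood / (q_liver_blood + fu_blood * cl_int_unbound)
    return cl, fh


def allocate_clearance(
    target_cl_over_f: float,
    fa: float,
    compound: CompoundParameters,
    q_liver_blood: float,
    fg: float = 1.0,
) -> ClearanceAllocation:
    """Retrograde clearance calculation from an oral-clearance target.

    Under the well-stirred liver model with hepatic-only elimination the oral
    (apparent) plasma clearance satisfies CL/F = fu * CLint_u / (fa * Fg), so
    the total unbound intrinsic clearance follows directly; it is split so
    that the forward-computed fraction metabolized by CYP3A4 equals
    ``compound.fm_cyp3a4`` (<= 0.08 for ivermectin), the remainder being
    biliary.  Running the allocation forward reproduces the target.
    """
    if not 0.0 < fa <= 1.0:
        raise ValueError("fa must be in (0, 1]")
    if target_cl_over_f <= 0:
        raise ValueError("target CL/F must be positive")
    fu_b = compound.fu_plasma / compound.blood_to_plasma
    cl_int_total = target_cl_over_f * fa * fg / compound.fu_plasma
    cl_b, fh = well_stirred_hepatic_cl(cl_int_total, fu_b, q_liver_blood)
    if cl_b >= 0.999 * q_liver_blood:
        raise ValueError(
            "infeasible target: hepatic clearance would exceed liver blood flow "
            f"(implied extraction {cl_b / q_liver_blood:.4f})"
        )
    return ClearanceAllocation(
        cl_int_met=compound.fm_cyp3a4 * cl_int_total,
        cl_int_bil=(1.0 - compound.fm_cyp3a4) * cl_int_total,
        cl_hepatic_blood=cl_b,
        fm_cyp3a4=compound.fm_cyp3a4,
        fh=fh,
    )
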