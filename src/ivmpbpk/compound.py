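"""Drug-specific parameter set: physicochemical, binding, permeability and
clearance inputs, plus the bile-micelle solubilization model used to
interconvert blank-buffer and biorelevant-media solubilities.

The shipped default is ivermectin, a neutral, highly lipophilic BCS class II
compound whose intestinal solubility is dominated by partitioning into bile
micelles.  Fields carry a provenance tag: measured in vitro values, physical
constants, or outputs of the calibration workflow (see ``ivmpbpk.calibrate``).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

#: molarity of water, mol/L; converts bile-salt molar ratios in the micelle term
WATER_MOLARITY = 55.3

IonizationClass = Literal["neutral", "monoprotic_acid", "monoprotic_base"]


class SolubilityMeasurement(BaseModel):
    """One equilibrium solubility measurement in a defined medium."""

    medium_label: str
    bile_salt_conc: float = Field(ge=0.0, description="mM")
    ph: float = Field(gt=0.0, lt=14.0)
    solubility: float = Field(gt=0.0, description="mg/mL")


class CompoundParameters(BaseModel):
    """Validated drug parameter set.

    Units: molecular_weight g/mol; solubilities mg/mL; particle_radius um;
    Papp 1e-6 cm/s; clearances L/h (unbound intrinsic, reference adult liver).
    """

    name: str = "compound"
    molecular_weight: float = Field(gt=0.0)
    log_p: float
    ionization_class: IonizationClass = "neutral"
    pka: list[float] = Field(default_factory=list)
    fu_plasma: float = Field(gt=0.0, le=1.0)
    blood_to_plasma: float = Field(gt=0.0)
    s_aq_intrinsic: float = Field(gt=0.0)
    km_w_unionized: float = Field(ge=0.0)
    particle_radius: float = Field(gt=0.0, description="um")
    particle_density: float = Field(default=1.2e3, gt=0.0, description="mg/cm^3")
    papp_caco2: float = Field(gt=0.0)
    papp_reference_caco2: float = Field(gt=0.0)
    efflux_ratio: float = Field(ge=0.0)
    efflux_active: bool = False  # hook only; negligible vs passive permeability
    fm_cyp3a4: float = Field(ge=0.0, le=1.0)
    cl_int_met: float = Field(ge=0.0)
    cl_biliary: float = Field(ge=0.0)
    cl_renal: float = Field(default=0.0, ge=0.0)
    kp_scalar: float = Field(default=1.0, gt=0.0)
    provenance: dict[str, str] = Field(default_factory=dict)

    @field_validator("pka")
    @classmethod
    def _pka_in_range(cls, v: list[float]) -> list[float]:
        for p in v:
            if not 0.0 < p < 14.0:
                raise ValueError(f"pka value {p} outside (0, 14)")
        return v

    @model_validator(mode="after")
    def _check_profile(self) -> "CompoundParameters":
        if self.ionization_class != "neutral" and not self.pka:
            raise ValueError("pka: ionizable compound requires at least one pKa")
        if self.name.lower() == "ivermectin":
            if self.fm_cyp3a4 > 0.08:
                raise ValueError(
                    "fm_cyp3a4: ivermectin profile requires fm_CYP3A4 <= 0.08 "
                    "(minor CYP3A4 contribution, clearance dominated by biliary "
                    f"excretion); got {self.fm_cyp3a4}"
                )
            if self.ionization_class != "neutral":
                raise ValueError(
                    "ionization_class: ivermectin is modeled as a neutral "
                    "species over intestinal pH"
                )
        if self.cl_int_met + self.cl_biliary + self.cl_renal <= 0.0:
            raise ValueError("cl_int_met/cl_biliary: total clearance must be > 0")
        return self

    # -- derived quantities -------------------------------------------------

    def diffusion_coefficient(self) -> float:
        """Aqueous diffusion coefficient, cm^2/h, from molecular weight.

        Empirical size correlation D[cm^2/s] = 9.9e-5 * MW^-0.453.
        """
        return 9.9e-5 * self.molecular_weight ** -0.453 * 3600.0

    def neutral_fraction(self, ph: float) -> float:
        """Fraction of the compound in the neutral species at the given pH."""
        if self.ionization_class == "neutral":
            return 1.0
        pka = self.pka[0]
        if self.ionization_class == "monoprotic_acid":
            return 1.0 / (1.0 + 10.0 ** (ph - pka))
        return 1.0 / (1.0 + 10.0 ** (pka - ph))


def _default_compound_path() -> Path:
    return Path(__file__).parent / "data" / "ivermectin.json"


def load_compound(config_path: str | Path | None = None) -> CompoundParameters:
    """Load and validate a compound parameter file (JSON or YAML).

    With no argument, loads the shipped calibrated ivermectin default.
    Validation failures raise ``ValueError`` naming the offending field.
    """
    path = Path(config_path) if config_path is not None else _default_compound_path()
    if not path.exists():
        raise FileNotFoundError(f"compound config not found: {path}")
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ValueError(f"compound config {path} did not parse to a mapping")
    try:
        return CompoundParameters(**raw)
    except Exception as exc:  # pydantic ValidationError carries field names
        raise ValueError(f"invalid compound config {path}: {exc}") from exc


def micelle_enhancement_ratio(
    blank: SolubilityMeasurement, biorelevant: SolubilityMeasurement
) -> float:
    """Fold-increase in solubility attributable to bile-salt micelles.

    Ratio of the biorelevant-media solubility (surfactants present) to the
    blank-buffer solubility at matched pH.
    """
    if blank.solubility <= 0.0:
        raise ValueError("blank solubility must be > 0")
    return biorelevant.solubility / blank.solubility


def fit_km_w(
    blank: SolubilityMeasurement,
    biorelevant: SolubilityMeasurement,
    cmc: float = 0.0,
) -> float:
    """Invert the micelle solubilization model for Km:w of the neutral species.

    Solves  S_bio = S_blank * (1 + Km:w * (CBS - CMC)/55.3 M)  for Km:w, so a
    forward evaluation of :func:`ivmpbpk.gut.segment_solubility` with the
    fitted value reproduces the biorelevant measurement exactly.

    Parameters
    ----------
    blank, biorelevant:
        Paired measurements without / with bile-salt surfactants.
    cmc:
        Critical micelle concentration, mM.  The biorelevant bile-salt
        concentration must exceed it, otherwise the micelle term is undefined.
    """
    micellar_mM = biorelevant.bile_salt_conc - cmc
    if micellar_mM <= 0.0:
        raise ValueError(
            "bile salt concentration must exceed the CMC to fit Km:w "
            f"(CBS={biorelevant.bile_salt_conc} mM, CMC={cmc} mM)"
        )
    ratio = micelle_enhancement_ratio(blank, biorelevant)
    km = (ratio - 1.0) * WATER_MOLARITY / (micellar_mM * 1e-3)
    return max(km, 0.0)
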