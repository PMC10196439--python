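"""Virtual-population generator.

Samples internally consistent virtual individuals - demographics, organ
volumes and blood flows, hepatic enzyme machinery, gut physiology - for three
populations: healthy (North-European-type) adult volunteers, Black African
adults, and African children (WHO-growth-chart-based demographics).

Scaling philosophy: lean-organ sizes track *frame* size (body surface area at
a normal-weight BMI for the subject's height and age), so that weight
differences at a given height land in adipose tissue.  Adipose volume is
derived from an age/sex/BMI body-fat relation, and the residual "rest of
body" closes the mass balance against whole-body volume.  This reproduces the
two clinically relevant couplings: higher BMI -> larger adipose volume ->
longer terminal half-life, and children's larger liver-per-kilogram -> higher
weight-normalized clearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .gut import GutPhysiology

Sex = Literal["male", "female"]

BSA_REF = 1.73  # m^2, scale anchor for the reference organ table
FRAME_BMI_ADULT = 23.0

#: reference lean-organ volumes (L) at frame BSA 1.73, and their scaling
#: exponents on relative frame BSA
_ORGAN_REF = {
    # tissue: (volume_L, exponent)
    "bone": (7.8, 1.5),
    "gut": (1.15, 1.176),
    "heart": (0.35, 1.176),
    "kidney": (0.32, 1.176),
    "liver": (1.69, 1.176),
    "lung": (0.55, 1.176),
    "muscle": (24.0, 1.8),
    "pancreas": (0.10, 1.176),
    "skin": (2.20, 1.5),
    "spleen": (0.19, 1.176),
    "reproductive": (0.05, 1.176),
}

#: fractions of cardiac output; liver receives hepatic-arterial plus the
#: splanchnic (gut + spleen + pancreas) venous return
FLOW_FRACTIONS = {
    "adipose": 0.075,
    "bone": 0.05,
    "brain": 0.12,
    "gut": 0.15,
    "heart": 0.04,
    "kidney": 0.18,
    "hepatic_artery": 0.065,
    "muscle": 0.17,
    "pancreas": 0.01,
    "skin": 0.05,
    "spleen": 0.03,
    "reproductive": 0.005,
    "rest": 0.055,
}

_BRAIN_AGE = np.array([0.0, 1.0, 2.0, 5.0, 10.0, 18.0, 90.0])
_BRAIN_VOL = np.array([0.45, 0.95, 1.15, 1.30, 1.40, 1.45, 1.45])

_FRAME_BMI_AGE = np.array([2.0, 5.0, 10.0, 15.0, 18.0, 25.0, 90.0])
_FRAME_BMI = np.array([16.0, 15.3, 16.6, 19.9, 21.7, 23.0, 23.0])

CYP3A4_ABUNDANCE_ADULT = 137.0  # pmol/mg microsomal protein
MPPGL = 40.0  # mg microsomal protein per g liver


def bsa_m2(weight_kg: float, height_cm: float) -> float:
    """Mosteller body surface area."""
    return float(np.sqrt(weight_kg * height_cm / 3600.0))


def cyp3a4_ontogeny(age_years: float, half_age_years: float = 0.4, hill: float = 2.0) -> float:
    """Fraction of adult CYP3A4 abundance at a given age.

    Sigmoidal (Hill) maturation, monotone non-decreasing, 50% of adult
    abundance at ``half_age_years``, plateau 1.0 in adulthood.
    """
    if age_years < 0:
        raise ValueError("age must be non-negative")
    a = age_years ** hill
    return a / (a + half_age_years ** hill)


def body_fat_fraction(age: float, sex: Sex, bmi: float) -> float:
    """Body-fat mass fraction from age/sex/BMI (Deurenberg-type relations)."""
    male = 1.0 if sex == "male" else 0.0
    if age < 15.0:
        pct = 1.51 * bmi - 0.70 * age - 3.6 * male + 1.4
    else:
        pct = 1.20 * bmi + 0.23 * min(age, 80.0) - 10.8 * male - 5.4
    return float(np.clip(pct, 5.0, 60.0)) / 100.0


@dataclass
class IndividualPhysiology:
    """One virtual subject: demographics plus derived physiology."""

    age: float
    sex: Sex
    weight: float  # kg
    height: float  # cm
    bmi: float
    bsa: float  # m^2
    frame_scale: float  # relative frame BSA driving lean-organ size
    cardiac_output: float  # L/h
    tissue_volumes: dict[str, float]  # L, the 14 perfusion-limited tissues
    tissue_flows: dict[str, float]  # L/h (liver = total inflow)
    blood_volume: float  # L
    plasma_volume: float  # L
    hematocrit: float
    albumin_g_l: float
    liver_volume: float  # L
    liver_mass_g: float
    mppgl: float = MPPGL
    cyp3a4_abundance: float = CYP3A4_ABUNDANCE_ADULT  # pmol/mg, subject value
    cyp3a4_rel: float = 1.0  # x reference total hepatic CYP3A4 (ontogeny, size, CV)
    cl_bil_scalar: float = 1.0  # x reference biliary intrinsic clearance
    bile_scalar: float = 1.0  # x population bile-salt concentrations

    @property
    def liver_blood_flow(self) -> float:
        return self.tissue_flows["liver"]

    def gut_physiology(self, prandial: str = "fasted", **fed_kwargs) -> GutPhysiology:
        base = (
            GutPhysiology.fed_adult(**fed_kwargs)
            if prandial == "fed"
            else GutPhysiology.fasted_adult()
        )
        return base.scaled(self.bsa / BSA_REF, self.bile_scalar)


def scale_organs(
    age: float, sex: Sex, weight: float, height: float
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Derive tissue volumes (L) and blood flows (L/h) from anthropometrics.

    Returns ``(volumes, flows, extras)`` where extras carries bsa, frame
    scale, blood/plasma volumes and hematocrit.  Raises ``ValueError`` for
    anthropometrics that leave a negative residual body volume.
    """
    if weight <= 0 or height <= 0:
        raise ValueError("implausible anthropometrics")
    bmi = weight / (height / 100.0) ** 2
    bsa = bsa_m2(weight, height)
    # lean-organ "frame": normal-weight BMI for age, except that organs of
    # lean subjects track their actual (lower) BMI, floored at 75% of normal
    fb_age = float(np.interp(age, _FRAME_BMI_AGE, _FRAME_BMI))
    frame_bmi = float(np.clip(bmi, 0.70 * fb_age, fb_age))
    frame_weight = frame_bmi * (height / 100.0) ** 2
    frame_bsa = bsa_m2(frame_weight, height)
    s = frame_bsa / BSA_REF

    volumes: dict[str, float] = {}
    for organ, (v_ref, expo) in _ORGAN_REF.items():
        volumes[organ] = v_ref * s ** expo
    if sex == "female" and age >= 15:
        volumes["muscle"] *= 0.75
        volumes["bone"] *= 0.85
        volumes["skin"] *= 0.90
    brain = float(np.interp(age, _BRAIN_AGE, _BRAIN_VOL))
    if sex == "female":
        brain *= 0.90
    volumes["brain"] = brain

    fat_frac = body_fat_fraction(age, sex, bmi)
    fat_mass = fat_frac * weight
    volumes["adipose"] = fat_mass / 0.736  # adipose tissue ~80% lipid, d=0.92

    if age < 15.0:
        blood = 0.075 * weight
    elif sex == "male":
        blood = 0.3669 * (height / 100.0) ** 3 + 0.03219 * weight + 0.6041
    else:
        blood = 0.3561 * (height / 100.0) ** 3 + 0.03308 * weight + 0.1833

    body_density = 1.0 / (fat_frac / 0.90 + (1.0 - fat_frac) / 1.10)
    total_volume = weight / body_density
    allocated = sum(volumes.values()) + blood
    rest = total_volume - allocated
    if rest < 0.5:
        # reconcile small residual deficits against muscle; reject large ones
        deficit = 0.5 - rest
        if deficit < 0.15 * total_volume and volumes["muscle"] > deficit + 1.0:
            volumes["muscle"] -= deficit
            rest = 0.5
        else:
            raise ValueError(
                f"infeasible anthropometrics: residual volume {rest:.2f} L "
                f"for weight {weight:.1f} kg, height {height:.1f} cm"
            )
    volumes["rest"] = rest

    co = 3.2 * bsa * 60.0  # L/h
    flows = {t: f * co for t, f in FLOW_FRACTIONS.items()}
    flows["liver"] = (
        flows.pop("hepatic_artery") + flows["gut"] + flows["spleen"] + flows["pancreas"]
    )
    hct = 0.37 if age < 12 else (0.43 if sex == "male" else 0.40)
    extras = {
        "bsa": bsa,
        "frame_scale": s,
        "blood_volume": blood,
        "plasma_volume": blood * (1.0 - hct),
        "hematocrit": hct,
        "cardiac_output": co,
    }
    return volumes, flows, extras


@dataclass
class PopulationSpec:
    """Distributional parameters defining one virtual population."""

    name: str
    age_range: tuple[float, float]
    proportion_female: float = 0.5
    # adult anthropometry: per-sex (height mean, height sd, BMI median, BMI cv)
    height_mean: dict[str, float] = field(default_factory=dict)
    height_sd: dict[str, float] = field(default_factory=dict)
    bmi_median: dict[str, float] = field(default_factory=dict)
    bmi_cv: dict[str, float] = field(default_factory=dict)
    growth_table: Optional[pd.DataFrame] = None  # pediatric populations
    bile_salt_cv: float = 0.35
    cyp3a4_mean: float = CYP3A4_ABUNDANCE_ADULT
    cyp3a4_cv: float = 0.40
    cl_bil_cv: float = 0.30
    albumin_adult_g_l: float = 45.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion_female <= 1.0:
            raise ValueError("proportion_female must be in [0,1]")
        if self.growth_table is not None:
            for sex in ("male", "female"):
                med = self.growth_table.query("sex == @sex").sort_values("age_years")
                if not med.weight_median_kg.is_monotonic_increasing:
                    raise ValueError("growth table weight medians must be monotone in age")

    @property
    def is_pediatric(self) -> bool:
        return self.growth_table is not None


def _growth_chart() -> pd.DataFrame:
    return pd.read_csv(Path(__file__).parent / "data" / "growth_charts.csv")


_POPULATIONS: dict[str, PopulationSpec] = {}


def get_population(name: str) -> PopulationSpec:
    """Look up a built-in population spec by name."""
    if not _POPULATIONS:
        _POPULATIONS["healthy_volunteer"] = PopulationSpec(
            name="healthy_volunteer",
            age_range=(18.0, 45.0),
            height_mean={"male": 176.0, "female": 163.0},
            height_sd={"male": 6.9, "female": 6.4},
            bmi_median={"male": 24.2, "female": 23.4},
            bmi_cv={"male": 0.13, "female": 0.13},
            albumin_adult_g_l=45.0,
        )
        _POPULATIONS["black_african_adult"] = PopulationSpec(
            name="black_african_adult",
            age_range=(18.0, 50.0),
            height_mean={"male": 168.0, "female": 158.0},
            height_sd={"male": 6.5, "female": 6.0},
            bmi_median={"male": 21.8, "female": 25.5},
            bmi_cv={"male": 0.15, "female": 0.20},
            albumin_adult_g_l=42.0,
        )
        _POPULATIONS["african_pediatric"] = PopulationSpec(
            name="african_pediatric",
            age_range=(2.0, 12.0),
            growth_table=_growth_chart(),
            albumin_adult_g_l=41.0,
        )
    if name not in _POPULATIONS:
        raise KeyError(f"unknown population {name!r}; choose from {sorted(_POPULATIONS)}")
    return _POPULATIONS[name]


#: anthropometric and biological covariate draws are truncated at +/- 3 SD,
#: the usual practice when building virtual populations (avoids physically
#: unrealizable bodies in the tails)
_Z_TRUNC = 3.0


def _truncated_normal(rng: np.random.Generator, z_trunc: float = _Z_TRUNC) -> float:
    return float(np.clip(rng.normal(), -z_trunc, z_trunc))


def _lognormal_multiplier(rng: np.random.Generator, cv: float) -> float:
    """Median-1 log-normal multiplier with the given coefficient of variation."""
    sigma = float(np.sqrt(np.log(1.0 + cv**2)))
    return float(np.exp(_truncated_normal(rng) * sigma))


def _sample_pediatric_anthropometrics(
    spec: PopulationSpec, age: float, sex: Sex, rng: np.random.Generator
) -> tuple[float, float]:
    tab = spec.growth_table.query("sex == @sex").sort_values("age_years")
    ages = tab.age_years.to_numpy(dtype=float)
    if not ages.min() <= age <= ages.max():
        raise ValueError(f"age {age} outside growth-table support [{ages.min()}, {ages.max()}]")
    w_med = float(np.interp(age, ages, tab.weight_median_kg))
    w_cv = float(np.interp(age, ages, tab.weight_cv))
    h_med = float(np.interp(age, ages, tab.height_median_cm))
    h_cv = float(np.interp(age, ages, tab.height_cv))
    z_w = _truncated_normal(rng)
    z_h = 0.7 * z_w + np.sqrt(1.0 - 0.7**2) * _truncated_normal(rng)
    weight = w_med * np.exp(z_w * np.sqrt(np.log(1 + w_cv**2)))
    height = h_med * np.exp(z_h * np.sqrt(np.log(1 + h_cv**2)))
    return float(weight), float(height)


def sample_individual(
    spec: PopulationSpec,
    rng: np.random.Generator,
    proportion_female: Optional[float] = None,
    age_range: Optional[tuple[float, float]] = None,
) -> IndividualPhysiology:
    """Draw one virtual subject; deterministic for a fixed generator state."""
    lo, hi = age_range if age_range is not None else spec.age_range
    age = float(rng.uniform(lo, hi))
    p_f = spec.proportion_female if proportion_female is None else proportion_female
    sex: Sex = "female" if rng.uniform() < p_f else "male"
    if spec.is_pediatric:
        weight, height = _sample_pediatric_anthropometrics(spec, age, sex, rng)
    else:
        height = spec.height_mean[sex] + spec.height_sd[sex] * _truncated_normal(rng)
        bmi = spec.bmi_median[sex] * _lognormal_multiplier(rng, spec.bmi_cv[sex])
        weight = bmi * (height / 100.0) ** 2
    bile = _lognormal_multiplier(rng, spec.bile_salt_cv)
    cyp_var = _lognormal_multiplier(rng, spec.cyp3a4_cv)
    bil_var = _lognormal_multiplier(rng, spec.cl_bil_cv)
    return build_individual(
        age, sex, weight, height,
        albumin=spec.albumin_adult_g_l,
        cyp3a4_variability=cyp_var,
        cl_bil_variability=bil_var,
        bile_scalar=bile,
    )


def build_individual(
    age: float,
    sex: Sex,
    weight: float,
    height: float,
    albumin: float = 45.0,
    cyp3a4_variability: float = 1.0,
    cl_bil_variability: float = 1.0,
    bile_scalar: float = 1.0,
) -> IndividualPhysiology:
    """Deterministic physiology from demographics plus variability multipliers."""
    volumes, flows, extras = scale_organs(age, sex, weight, height)
    liver_v = volumes["liver"]
    liver_ref_v = _reference_liver_volume()
    ontogeny = cyp3a4_ontogeny(age)
    return IndividualPhysiology(
        age=age,
        sex=sex,
        weight=weight,
        height=height,
        bmi=weight / (height / 100.0) ** 2,
        bsa=extras["bsa"],
        frame_scale=extras["frame_scale"],
        cardiac_output=extras["cardiac_output"],
        tissue_volumes=volumes,
        tissue_flows=flows,
        blood_volume=extras["blood_volume"],
        plasma_volume=extras["plasma_volume"],
        hematocrit=extras["hematocrit"],
        albumin_g_l=albumin,
        liver_volume=liver_v,
        liver_mass_g=liver_v * 1000.0 * 1.05,
        cyp3a4_abundance=CYP3A4_ABUNDANCE_ADULT * ontogeny * cyp3a4_variability,
        cyp3a4_rel=(liver_v / liver_ref_v) * ontogeny * cyp3a4_variability,
        cl_bil_scalar=(liver_v / liver_ref_v) * cl_bil_variability,
        bile_scalar=bile_scalar,
    )


_REFERENCE_ADULT = {"age": 30.0, "sex": "male", "weight": 77.0, "height": 176.0}


def _reference_liver_volume() -> float:
    volumes, _, _ = scale_organs(**_REFERENCE_ADULT)  # type: ignore[arg-type]
    return volumes["liver"]


def reference_adult() -> IndividualPhysiology:
    """The deterministic reference adult anchoring the clearance calibration."""
    return build_individual(**_REFERENCE_ADULT)  # type: ignore[arg-type]


def reference_child(age: float = 3.5) -> IndividualPhysiology:
    """Deterministic reference pre-school child (growth-chart medians, boy)."""
    spec = get_population("african_pediatric")
    tab = spec.growth_table.query("sex == 'male'").sort_values("age_years")
    ages = tab.age_years.to_numpy(dtype=float)
    weight = float(np.interp(age, ages, tab.weight_median_kg))
    height = float(np.interp(age, ages, tab.height_median_cm))
    return build_individual(age, "male", weight, height, albumin=41.0)


def sample_cohort(
    spec: PopulationSpec,
    n: int,
    seed_seq: np.random.SeedSequence,
    proportion_female: Optional[float] = None,
    age_range: Optional[tuple[float, float]] = None,
) -> list[IndividualPhysiology]:
    """Sample n subjects with one independent RNG stream per subject, so a
    cohort edit never reshuffles other subjects."""
    children = seed_seq.spawn(n)
    return [
        sample_individual(
            spec, np.random.default_rng(s), proportion_female, age_range
        )
        for s in children
    ]
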