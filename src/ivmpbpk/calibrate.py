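"""Calibration workflow for the ivermectin parameter set.

The published in vitro record fixes the measured quantities (biorelevant and
blank solubilities, Caco-2 permeability with its propranolol control, the
fm_CYP3A4 ceiling); the remaining drug inputs are identified against the
clinical observations in a fixed order, absorption before disposition:

1. Km:w,unionized from the FaSSIF/SIF solubility pair (exact inversion).
2. Particle radius, within 1-50 um, so the fasted reference-adult fraction
   absorbed at 12 mg matches the 0.52 operating point of the fa-dose curve.
3. Systemic (biliary + minor CYP3A4) intrinsic clearance so the simulated
   healthy-volunteer trial exposures sit inside the printed accuracy
   envelopes of the observed 12 mg and 30 mg AUC(0,72) values.
4. kp_scalar (and log P within 3.5-5.5) so the 30 mg terminal half-life and
   peak-concentration level match the observed clinical values.

Step outputs are frozen into ``data/ivermectin.json``; running this module
(see ``analysis/01_calibrate_absorption.py``) re-derives them and reports the
residuals of the shipped configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .compound import CompoundParameters, SolubilityMeasurement, fit_km_w
from .engine import build_model, simulate
from .gut import GutPhysiology, simulate_gut
from .nca import pk_metrics
from .population import reference_adult
from .trials import DEFAULT_SAMPLING, replace_compound

#: FaSSIF / blank-buffer solubility pair (mg/mL at pH 6.5, 3 mM bile salt)
FASSIF_PAIR = (
    SolubilityMeasurement(medium_label="SIF-blank", bile_salt_conc=0.0, ph=6.5, solubility=0.0007),
    SolubilityMeasurement(medium_label="FaSSIF", bile_salt_conc=3.0, ph=6.5, solubility=0.12),
)
#: the independent second report of the same experiment
FASSIF_PAIR_ALT = (
    SolubilityMeasurement(medium_label="FaSSIF-blank", bile_salt_conc=0.0, ph=6.5, solubility=0.000175),
    SolubilityMeasurement(medium_label="FaSSIF", bile_salt_conc=3.0, ph=6.5, solubility=0.0142),
)


def calibrate_km_w(compound: CompoundParameters) -> CompoundParameters:
    """Step 1: bile-micelle partition coefficient from the measured pair."""
    km = fit_km_w(*FASSIF_PAIR, cmc=0.0)
    return replace_compound(compound, km_w_unionized=km, s_aq_intrinsic=FASSIF_PAIR[0].solubility)


def calibrate_particle_radius(
    compound: CompoundParameters,
    fa_target: float = 0.52,
    dose_mg: float = 12.0,
    bounds: tuple[float, float] = (1.0, 50.0),
) -> CompoundParameters:
    """Step 2: particle radius hitting the fasted reference fa at 12 mg."""
    gut = GutPhysiology.fasted_adult()

    def resid(r: float) -> float:
        return simulate_gut(replace_compound(compound, particle_radius=r), gut, dose_mg).fa - fa_target

    lo, hi = bounds
    if resid(lo) < 0 or resid(hi) > 0:
        raise ValueError("fa target not bracketed by the admissible radius range")
    r = brentq(resid, lo, hi, xtol=0.05)
    return replace_compound(compound, particle_radius=float(r))


def _reference_metrics(compound: CompoundParameters, dose_mg: float):
    ref = reference_adult()
    profile = simulate(build_model(ref, compound), dose_mg)
    return pk_metrics(profile, DEFAULT_SAMPLING)


def calibrate_clearance(
    compound: CompoundParameters,
    auc30_reference_target: float = 1330.0,
    n_iter: int = 3,
) -> CompoundParameters:
    """Step 3: scale intrinsic clearance to the 30 mg AUC(0,72) anchor.

    The anchor is the reference-adult value whose matched virtual-trial mean
    lies inside both the 12 mg (1.31-fold of 513) and 30 mg (1.23-fold of
    1724) observed envelopes; exposure scales essentially inversely with
    clearance, so a short fixed-point iteration suffices.  The fm_CYP3A4
    split is preserved.
    """
    c = compound
    for _ in range(n_iter):
        auc = _reference_metrics(c, 30.0).auc_0_t
        f = auc / auc30_reference_target
        c = replace_compound(c, cl_int_met=c.cl_int_met * f, cl_biliary=c.cl_biliary * f)
    return c


def calibrate_distribution(
    compound: CompoundParameters,
    t_half_target: float = 20.1,
    log_p_grid: tuple[float, ...] = (4.0, 4.1, 4.2, 4.3, 4.4),
    kp_grid: tuple[float, ...] = (0.044, 0.048, 0.052, 0.056, 0.060),
    cmax30_observed: float = 84.8,
) -> CompoundParameters:
    """Step 4: pick (log P, kp_scalar) for the 30 mg half-life and peak.

    Grid search minimizing the squared log-residuals of the reference-adult
    30 mg terminal half-life against the observed 20.1 h and of the peak
    concentration against the observed level (the reference individual runs
    ~15% below the matched mixed-sex trial mean, which the objective
    anticipates); clearance is re-anchored at each candidate.
    """
    best, best_cost = compound, np.inf
    for lp in log_p_grid:
        for ks in kp_grid:
            cand = calibrate_clearance(replace_compound(compound, log_p=lp, kp_scalar=ks))
            m = _reference_metrics(cand, 30.0)
            if not np.isfinite(m.t_half):
                continue
            cost = np.log(m.t_half / t_half_target) ** 2 + np.log(
                m.cmax / (0.87 * cmax30_observed)
            ) ** 2
            if cost < best_cost:
                best, best_cost = cand, cost
    return best


@dataclass
class CalibrationReport:
    compound: CompoundParameters
    fa_12mg: float
    fa_2p6mg_child: float
    auc72_30mg: float
    cmax_30mg: float
    t_half_30mg: float


def run_calibration(start: CompoundParameters) -> CalibrationReport:
    """Execute the full workflow and report the headline diagnostics."""
    c = calibrate_km_w(start)
    c = calibrate_particle_radius(c)
    c = calibrate_distribution(c)
    c = calibrate_clearance(c)
    from .population import reference_child

    gut_child = reference_child().gut_physiology("fasted")
    m30 = _reference_metrics(c, 30.0)
    return CalibrationReport(
        compound=c,
        fa_12mg=simulate_gut(c, GutPhysiology.fasted_adult(), 12.0).fa,
        fa_2p6mg_child=simulate_gut(c, gut_child, 2.6).fa,
        auc72_30mg=m30.auc_0_t,
        cmax_30mg=m30.cmax,
        t_half_30mg=m30.t_half,
    )
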