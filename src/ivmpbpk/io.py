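"""File I/O, run manifests, and deterministic test fixtures.

Every numeric CSV column carries its unit in the header; manifests record the
inputs and seeds needed to replay a run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import __version__
from .compound import CompoundParameters, load_compound
from .engine import ConcentrationProfile
from .population import get_population, sample_cohort
from .trials import StudyDesign, TrialResult, run_trial

_UNIT_COLUMNS = {
    "cmax": "cmax_ng_per_mL",
    "tmax": "tmax_h",
    "auc_0_t": "auc_0_72_ng_h_per_mL",
    "auc_0_inf": "auc_0_inf_ng_h_per_mL",
    "t_half": "t_half_h",
    "fa": "fa_fraction",
    "weight": "weight_kg",
    "age": "age_years",
    "bmi": "bmi_kg_per_m2",
    "dose_mg": "dose_mg",
}


def load_observed_table() -> pd.DataFrame:
    """Observed clinical reference values (transcribed summary table)."""
    return pd.read_csv(Path(__file__).parent / "data" / "observed_clinical.csv")


def _design_to_dict(design: StudyDesign) -> dict[str, Any]:
    d = asdict(design)
    d["sampling_times"] = list(map(float, design.sampling_times))
    return d


def design_from_dict(d: dict[str, Any]) -> StudyDesign:
    d = dict(d)
    d["sampling_times"] = np.asarray(d["sampling_times"], dtype=float)
    if d.get("age_range") is not None:
        d["age_range"] = tuple(d["age_range"])
    return StudyDesign(**d)


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def write_outputs(
    result: TrialResult | ConcentrationProfile | pd.DataFrame,
    out_dir: str | Path,
    label: str = "run",
    seed: Optional[int] = None,
    compound: Optional[CompoundParameters] = None,
) -> dict[str, str]:
    """Write a result bundle plus a replayable JSON manifest.

    Returns the file inventory (name -> path).  Partial writes are cleaned
    up on failure.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inventory: dict[str, str] = {}
    written: list[Path] = []
    try:
        if isinstance(result, TrialResult):
            subj = result.subjects.rename(columns=_UNIT_COLUMNS)
            p = out / f"{label}_subjects.csv"
            subj.to_csv(p, index=False)
            written.append(p)
            inventory["subjects"] = str(p)
            summ = result.summary().rename(index=_UNIT_COLUMNS)
            p = out / f"{label}_summary.csv"
            summ.to_csv(p, index_label="metric")
            written.append(p)
            inventory["summary"] = str(p)
            manifest: dict[str, Any] = {"design": _design_to_dict(result.design)}
        elif isinstance(result, ConcentrationProfile):
            p = out / f"{label}_profile.csv"
            result.to_frame().to_csv(p, index=False)
            written.append(p)
            inventory["profile"] = str(p)
            manifest = {"dose_mg": result.dose_mg}
        elif isinstance(result, pd.DataFrame):
            p = out / f"{label}_curve.csv"
            result.to_csv(p, index=False)
            written.append(p)
            inventory["curve"] = str(p)
            manifest = {}
        else:
            raise TypeError(f"unsupported result type {type(result)!r}")
        manifest.update(
            {
                "label": label,
                "seed": seed,
                "package_version": __version__,
                "timestamp_utc": datetime.now(timezone.utc).isoformat(),
                "inventory": inventory,
            }
        )
        if compound is not None:
            cfg = compound.model_dump_json()
            manifest["compound"] = json.loads(cfg)
            manifest["compound_sha256"] = _sha256(cfg)
        p = out / f"{label}_manifest.json"
        p.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        inventory["manifest"] = str(p)
        # append-only run log
        with (out / "run_log.txt").open("a") as fh:
            fh.write(f"{manifest['timestamp_utc']}\t{label}\tseed={seed}\n")
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return inventory


def replay_manifest(manifest_path: str | Path, out_dir: str | Path) -> dict[str, str]:
    """Re-run a trial manifest; stored seeds make the outputs bit-identical."""
    m = json.loads(Path(manifest_path).read_text())
    if "design" not in m:
        raise ValueError("manifest does not describe a trial run")
    design = design_from_dict(m["design"])
    compound = CompoundParameters(**m["compound"]) if "compound" in m else load_compound()
    result = run_trial(design, compound, seed=m["seed"])
    return write_outputs(result, out_dir, label=m["label"], seed=m["seed"], compound=compound)


# ---------------------------------------------------------------------------
# deterministic fixtures for the test suite (generated, never downloaded)
# ---------------------------------------------------------------------------

TOY_COMPOUNDS: dict[str, dict[str, Any]] = {
    # freely soluble, highly permeable neutral probe: no absorption limitation
    "toy_soluble_neutral": {
        "name": "toy_soluble_neutral",
        "molecular_weight": 300.0,
        "log_p": 2.0,
        "ionization_class": "neutral",
        "pka": [],
        "fu_plasma": 0.5,
        "blood_to_plasma": 1.0,
        "s_aq_intrinsic": 50.0,
        "km_w_unionized": 0.0,
        "particle_radius": 5.0,
        "papp_caco2": 62.1,
        "papp_reference_caco2": 62.1,
        "efflux_ratio": 1.0,
        "fm_cyp3a4": 0.5,
        "cl_int_met": 20.0,
        "cl_biliary": 20.0,
        "kp_scalar": 1.0,
    },
    "toy_weak_acid": {
        "name": "toy_weak_acid",
        "molecular_weight": 250.0,
        "log_p": 1.5,
        "ionization_class": "monoprotic_acid",
        "pka": [5.0],
        "fu_plasma": 0.2,
        "blood_to_plasma": 0.8,
        "s_aq_intrinsic": 0.05,
        "km_w_unionized": 1.0e4,
        "particle_radius": 10.0,
        "papp_caco2": 30.0,
        "papp_reference_caco2": 62.1,
        "efflux_ratio": 1.0,
        "fm_cyp3a4": 0.3,
        "cl_int_met": 10.0,
        "cl_biliary": 5.0,
        "kp_scalar": 1.0,
    },
    "toy_weak_base": {
        "name": "toy_weak_base",
        "molecular_weight": 320.0,
        "log_p": 2.5,
        "ionization_class": "monoprotic_base",
        "pka": [6.5],
        "fu_plasma": 0.3,
        "blood_to_plasma": 1.1,
        "s_aq_intrinsic": 0.1,
        "km_w_unionized": 5.0e4,
        "particle_radius": 8.0,
        "papp_caco2": 90.0,
        "papp_reference_caco2": 62.1,
        "efflux_ratio": 1.2,
        "fm_cyp3a4": 0.4,
        "cl_int_met": 15.0,
        "cl_biliary": 10.0,
        "kp_scalar": 1.0,
    },
}


def generate_fixtures(seed: int, out_dir: str | Path) -> dict[str, str]:
    """Emit the deterministic fixture bundle used by the test suite.

    Small cohorts (n = 5) per population, the observed-values table, and the
    toy compound configs.  Byte-identical for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inventory: dict[str, str] = {}
    for pop_idx, pop in enumerate(
        ("healthy_volunteer", "black_african_adult", "african_pediatric")
    ):
        spec = get_population(pop)
        cohort = sample_cohort(spec, 5, np.random.SeedSequence([seed, pop_idx]))
        df = pd.DataFrame(
            [
                {
                    "age_years": s.age,
                    "sex": s.sex,
                    "weight_kg": s.weight,
                    "height_cm": s.height,
                    "bmi_kg_per_m2": s.bmi,
                    "cardiac_output_L_per_h": s.cardiac_output,
                    "liver_volume_L": s.liver_volume,
                    "adipose_volume_L": s.tissue_volumes["adipose"],
                    "cyp3a4_rel": s.cyp3a4_rel,
                    "cl_bil_scalar": s.cl_bil_scalar,
                    "bile_scalar": s.bile_scalar,
                }
                for s in cohort
            ]
        )
        p = out / f"cohort_{pop}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        inventory[f"cohort_{pop}"] = str(p)
    p = out / "observed_clinical.csv"
    load_observed_table().to_csv(p, index=False)
    inventory["observed"] = str(p)
    for name, cfg in TOY_COMPOUNDS.items():
        p = out / f"{name}.json"
        p.write_text(json.dumps(cfg, indent=2, sort_keys=True))
        inventory[name] = str(p)
    return inventory
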