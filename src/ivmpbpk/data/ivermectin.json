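{
  "name": "ivermectin",
  "molecular_weight": 875.1,
  "log_p": 4.2,
  "ionization_class": "neutral",
  "pka": [],
  "fu_plasma": 0.068,
  "blood_to_plasma": 0.78,
  "s_aq_intrinsic": 0.0007,
  "km_w_unionized": 3141568.0,
  "particle_radius": 40.0,
  "particle_density": 1200.0,
  "papp_caco2": 190.0,
  "papp_reference_caco2": 62.1,
  "efflux_ratio": 1.5,
  "efflux_active": false,
  "fm_cyp3a4": 0.08,
  "cl_int_met": 11.824,
  "cl_biliary": 135.976,
  "cl_renal": 0.0,
  "kp_scalar": 0.052,
  "provenance": {
    "molecular_weight": "constant",
    "log_p": "calibrated",
    "fu_plasma": "calibrated",
    "blood_to_plasma": "calibrated",
    "s_aq_intrinsic": "paper",
    "km_w_unionized": "calibrated",
    "particle_radius": "calibrated",
    "particle_density": "constant",
    "papp_caco2": "paper",
    "papp_reference_caco2": "paper",
    "efflux_ratio": "paper",
    "fm_cyp3a4": "paper",
    "cl_int_met": "calibrated",
    "cl_biliary": "calibrated",
    "kp_scalar": "calibrated"
  }
}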