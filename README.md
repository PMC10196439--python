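# ivmpbpk — whole-body PBPK model of oral ivermectin

Ivermectin is the mainstay of mass-drug-administration programs against
onchocerciasis and lymphatic filariasis, and is under study at higher and
repeated doses as a mosquito-lethal endectocide for malaria transmission
control. Its oral pharmacokinetics are awkward: the molecule is a highly
permeable but very poorly water-soluble lactone (BCS class II) whose
intestinal absorption rides almost entirely on bile-micelle-mediated
solubilization, and its high lipophilicity ties plasma exposure to body
composition. This package implements, as open and testable Python, a
mechanistic whole-body physiologically-based pharmacokinetic (PBPK) model of
single oral doses of ivermectin, for modelers who need to reason about dose
extrapolation (adults to children, fasted to fed, reference to African
populations) rather than fit empirical compartments.

The model has three mechanistic layers:

- **Absorption** — a nine-segment compartmental transit model of the gut
  lumen (stomach, duodenum, two jejunal and four ileal segments, colon).
  Solid drug transits and dissolves with Wang–Flanagan spherical-particle
  kinetics against the local saturation solubility
  `S_total = S_aq(pH) · [1 + Km:w · max(0, CBS − CMC)/55.3 M]`,
  where the bile-micelle partition coefficient of the neutral species
  (Km:w ≈ 3.14×10⁶) is fitted exactly to the measured 171-fold
  solubility enhancement in biorelevant (FaSSIF) versus blank intestinal
  medium. Dissolved drug is absorbed with regional rate constants
  `ka = 2·Peff/R`, with the human jejunal effective permeability obtained by
  one-point Caco-2 calibration against propranolol (Papp 190 vs
  62.1 ×10⁻⁶ cm/s). The fraction absorbed (fa) and its dose, prandial-state
  and age dependence are emergent.
- **Disposition** — a 14-tissue perfusion-limited model with tissue:plasma
  partition coefficients from the tissue-composition (Rodgers–Rowland-type)
  equations for a neutral compound, a vegetable-oil:water coefficient for
  adipose, and one global calibrated Kp scalar. Elimination is hepatic only:
  ≤8% of systemic clearance through CYP3A4 (so enzyme ontogeny matters
  little) and the rest as biliary excretion into a cumulative bile sink.
- **Virtual populations** — healthy (European-type) adults, Black African
  adults, and African children on WHO-style growth charts, with internally
  consistent organ volumes and flows, body-composition-driven adipose
  volume, CYP3A4 ontogeny, and log-normal between-subject variability in
  bile salts, enzyme abundance and biliary clearance. Virtual trials
  replicate the designs of the published clinical studies (10 trials of
  matched cohorts each).

## Worked example

```python
import ivmpbpk as pk

compound = pk.load_compound()               # calibrated ivermectin defaults
gut = pk.GutPhysiology.fasted_adult()
print(round(pk.simulate_gut(compound, gut, 12.0).fa, 3))   # 0.555

adult = pk.reference_adult()
profile = pk.simulate(pk.build_model(adult, compound), 30.0)
m = pk.pk_metrics(profile, pk.trials.DEFAULT_SAMPLING)
print(round(m.cmax, 1), m.tmax, round(m.auc_0_t), round(m.t_half, 1))
# 77.9 4.0 1318 19.0
```

A fasted reference adult absorbs about 55% of a 12 mg dose; at 30 mg the
simulated peak concentration is ~78 ng/mL at 4 h, the 72-h exposure
~1320 ng·h/mL and the apparent terminal half-life ~19 h for the reference
individual (matched virtual-trial means run some 5–10% higher) — against
observed values of 84.8 ng/mL, 4.6 h, 1724 ng·h/mL and 20.1 h for that
study.

The numbered scripts under `analysis/` run the full study sequence —
calibration audit, fa–dose and solubility-sensitivity curves, adult and
pediatric virtual trials, the food effect, and the BMI–half-life
association — and write tidy tables under `results/`. For example:

```bash
python analysis/04_food_effect.py
# fed/fasted AUC(0,72) ratio at 30 mg: 2.07 (reported prediction 2.2, observed 2.6)
```

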