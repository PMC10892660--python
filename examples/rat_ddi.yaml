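# Rat CYP3A drug-drug-interaction scenario: saxagliptin 5 mg/kg oral (victim)
# co-administered with nicardipine 15 mg/kg oral (perpetrator, competitive CYP3A2
# inhibitor). Run with:
#   pbpkddi run --config examples/rat_ddi.yaml --out out/
species: rat
body_weight_kg: 0.25
duration_h: 24.0
seed: 1
victim:
  compound: saxagliptin
  doses:
    - {route: oral, amount: 5.0, per_kg: true}
perpetrator:
  compound: nicardipine
  doses:
    - {route: oral, amount: 15.0, per_kg: true}
inhibitor_source: liver_intracellular_unbound
sensitivity_parameters:
  - victim.fraction_unbound
  - victim.clearance.CYP3A2.clint_ul_min_pmol
  - victim.clearance.renal.clearance_ml_min_kg
  - perpetrator.inhibition.CYP3A2.ki_um
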