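# Saxagliptin (DPP-4 inhibitor; CYP3A-metabolized victim drug). Model input values; the
# lipophilicity and intestinal permeability entries are the fitted model inputs, not the raw
# literature values.
name: saxagliptin
molecular_weight_g_mol: 315.41
lipophilicity_logd74: -0.7
pka: 7.9
pka_type: base
solubility_mg_ml: 17.6
solubility_ref_ph: 7.0
fraction_unbound:
  rat: 0.82
  human: 1.0
specific_intestinal_permeability_cm_s: 1.7e-6
cellular_permeability: 13.0
cellular_permeability_unit: 1e-6 cm/s
clearance:
  - kind: enzyme_mediated
    species: rat
    enzyme: CYP3A2
    clint_ul_min_pmol: 1.99
  - kind: enzyme_mediated
    species: human
    enzyme: CYP3A4
    clint_ul_min_pmol: 0.38
  - kind: enzyme_mediated
    species: human
    enzyme: CYP3A5
    clint_ul_min_pmol: 0.09
  - kind: renal
    species: rat
    clearance_ml_min_kg: 38.0
  - kind: renal
    species: human
    clearance_ml_min_kg: 1.9
formulations:
  - name: solution
    kind: solution
  - name: tablet_2.5mg
    kind: tablet
    dissolution_shape: 0.68
    dissolution_time_min: 120.5
  - name: tablet_5mg
    kind: tablet
    dissolution_shape: 0.8
    dissolution_time_min: 71.0
inhibition: []
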