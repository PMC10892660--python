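# Nicardipine (dihydropyridine calcium-channel blocker; competitive CYP3A inhibitor,
# perpetrator drug). Hepatic elimination is entered as a plasma-referenced half-life
# (see docs/methods.md). The cellular permeability unit is carried as printed (cm/s);
# set cellular_permeability_unit to "1e-6 cm/s" to select the alternative reading.
name: nicardipine
molecular_weight_g_mol: 479.59
lipophilicity_logd74: 4.6
pka: 8.1
pka_type: base
solubility_mg_ml: 7.9
solubility_ref_ph: 7.0
fraction_unbound:
  rat: 0.084
  human: 0.01
specific_intestinal_permeability_cm_s: 1.15e-6
cellular_permeability: 0.09
cellular_permeability_unit: cm/s
clearance:
  - kind: total_hepatic_halflife
    species: rat
    hepatic_t_half_min: 0.62
  - kind: total_hepatic_halflife
    species: human
    hepatic_t_half_min: 4.5
formulations:
  - name: solution
    kind: solution
  - name: tablet
    kind: tablet
    dissolution_shape: 1.18
    dissolution_time_min: 5.59
inhibition:
  - enzyme: CYP3A2
    species: rat
    ki_um: 0.39
    mechanism: competitive
  - enzyme: CYP3A4
    species: human
    ki_um: 0.06
    mechanism: competitive
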