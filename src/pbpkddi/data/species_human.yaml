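# Species-level reference parameters, human adult (v1). All values overridable via load_physiology().
species: human
reference_body_weight_kg: 70.0
co_allometric_coef: 235.0
co_allometric_exp: 0.75
hematocrit: 0.45
arterial_blood_fraction_bw: 0.0290
venous_blood_fraction_bw: 0.0500
# liver microsomal scaling: mg microsomal protein per g liver (literature default; the
# corresponding rat value is experimental)
mppgl_mg_per_g: 40.0
# enzyme reference concentrations, pmol per mg microsomal protein (literature population means)
enzyme_reference_concentration_pmol_per_mg:
  CYP3A4: 137.0
  CYP3A5: 24.0
gfr_ml_min_kg: 1.8
gi:
  stomach_volume_ml: 50.0
  gastric_emptying_thalf_min: 15.0
  si_volumes_ml: [35.0, 35.0, 35.0]
  si_segment_mrt_min: [66.0, 66.0, 66.0]
  si_surface_areas_cm2: [50000.0, 30000.0, 20000.0]
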