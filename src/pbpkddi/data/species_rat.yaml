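# Species-level reference parameters, rat (v1). All values overridable via load_physiology().
species: rat
reference_body_weight_kg: 0.25
# cardiac output (mL/min) = co_allometric_coef * BW_kg ** co_allometric_exp
co_allometric_coef: 235.0
co_allometric_exp: 0.75
hematocrit: 0.45
# blood pools as fraction of body weight (density 1 g/mL); together with the organ vascular
# spaces these make up total blood.
arterial_blood_fraction_bw: 0.0272
venous_blood_fraction_bw: 0.0468
# liver microsomal scaling: mg microsomal protein per g liver
mppgl_mg_per_g: 44.8
# enzyme reference concentrations, pmol per mg microsomal protein
enzyme_reference_concentration_pmol_per_mg:
  CYP3A2: 101.0
gfr_ml_min_kg: 5.2
gi:
  stomach_volume_ml: 3.4
  gastric_emptying_thalf_min: 10.0
  # three small-intestine transit segments
  si_volumes_ml: [1.7, 1.7, 1.7]
  # mean residence time per segment (min); transit rate = 1/mrt
  si_segment_mrt_min: [20.0, 20.0, 20.0]
  # effective absorptive surface area per segment (cm^2), villi amplification included
  si_surface_areas_cm2: [800.0, 480.0, 320.0]
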