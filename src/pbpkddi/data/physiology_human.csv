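# Reference human (adult, 70 kg) organ table, v1. Column semantics identical to physiology_rat.csv.
# Sources: standard reference-man compilations (ICRP/Brown et al.-style fraction tables);
# surface-area densities are package defaults, overridable.
organ,volume_fraction_bw,flow_fraction_co,f_vascular,f_interstitial,f_intracellular,f_water,f_lipid,f_protein,sa_endothelial_cm2_per_ml,sa_cell_cm2_per_ml,drains_to,enzymes
lung,0.0076,1.0,0.18,0.18,0.64,0.79,0.015,0.15,2500,30000,arterial,
heart,0.0047,0.040,0.06,0.15,0.79,0.78,0.025,0.15,500,30000,venous,
brain,0.0200,0.120,0.03,0.04,0.93,0.77,0.110,0.08,240,30000,venous,
muscle,0.4000,0.170,0.03,0.12,0.85,0.76,0.022,0.17,350,30000,venous,
adipose,0.2140,0.050,0.02,0.13,0.85,0.15,0.800,0.05,120,30000,venous,
skin,0.0371,0.050,0.05,0.30,0.65,0.65,0.130,0.22,120,30000,venous,
bone,0.1429,0.050,0.04,0.10,0.86,0.43,0.070,0.20,120,30000,venous,
liver,0.0257,0.065,0.11,0.16,0.73,0.72,0.065,0.18,25000,30000,venous,CYP3A4:1.0;CYP3A5:1.0
spleen,0.0026,0.030,0.22,0.15,0.63,0.78,0.025,0.18,25000,30000,portal,
gut_wall,0.0171,0.160,0.07,0.18,0.75,0.75,0.050,0.15,500,30000,portal,
kidney,0.0044,0.190,0.10,0.20,0.70,0.78,0.040,0.16,15000,30000,venous,
gonads,0.0005,0.0005,0.05,0.15,0.80,0.80,0.020,0.13,240,30000,venous,
rest_of_body,0.0444,0.0745,0.04,0.15,0.81,0.75,0.050,0.15,240,30000,venous,
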