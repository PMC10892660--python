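# Reference rat (Sprague-Dawley, 0.25 kg) organ table, v1.
# volume_fraction_bw: organ volume as fraction of body weight (density 1 g/mL assumed).
# flow_fraction_co: organ blood flow as fraction of cardiac output; liver row is the hepatic
#   artery only (portal inflow = gut_wall + spleen outflows); lung carries full cardiac output.
# f_vascular/f_interstitial/f_intracellular: sub-compartment volume fractions (sum <= 1).
# f_water/f_lipid/f_protein: bulk tissue composition used for partitioning.
# sa_*: exchange surface-area densities per mL tissue (endothelial barrier, cell membrane barrier).
# drains_to: venous | portal | arterial (lung). The rest_of_body row closes volume/flow balance
#   exactly at load time; stored fractions for it are nominal.
# Sources: standard reference compilations of rat anatomy/physiology (Brown et al.-style fraction
#   tables); surface-area densities are package defaults, overridable.
organ,volume_fraction_bw,flow_fraction_co,f_vascular,f_interstitial,f_intracellular,f_water,f_lipid,f_protein,sa_endothelial_cm2_per_ml,sa_cell_cm2_per_ml,drains_to,enzymes
lung,0.0050,1.0,0.18,0.18,0.64,0.79,0.015,0.15,2500,30000,arterial,
heart,0.0033,0.049,0.06,0.15,0.79,0.78,0.025,0.15,500,30000,venous,
brain,0.0057,0.020,0.03,0.04,0.93,0.77,0.110,0.08,240,30000,venous,
muscle,0.4040,0.278,0.03,0.12,0.85,0.76,0.022,0.17,350,30000,venous,
adipose,0.0700,0.070,0.02,0.13,0.85,0.15,0.800,0.05,120,30000,venous,
skin,0.1900,0.058,0.05,0.30,0.65,0.65,0.130,0.22,120,30000,venous,
bone,0.0730,0.122,0.04,0.10,0.86,0.43,0.070,0.20,120,30000,venous,
liver,0.0366,0.021,0.11,0.16,0.73,0.72,0.065,0.18,25000,30000,venous,CYP3A2:1.0
spleen,0.0020,0.0122,0.22,0.15,0.63,0.78,0.025,0.18,25000,30000,portal,
gut_wall,0.0270,0.131,0.07,0.18,0.75,0.75,0.050,0.15,500,30000,portal,
kidney,0.0073,0.141,0.10,0.20,0.70,0.78,0.040,0.16,15000,30000,venous,
gonads,0.0025,0.005,0.05,0.15,0.80,0.80,0.020,0.13,240,30000,venous,
rest_of_body,0.0996,0.0928,0.04,0.15,0.81,0.75,0.050,0.15,240,30000,venous,
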