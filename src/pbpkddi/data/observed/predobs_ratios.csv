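# Printed per-study predicted/observed PK parameter ratios with the per-study concentration
# MRD, grouped as printed (one GMFE per species x compound x parameter, see gmfe_reference.csv).
compound,species,study,mrd,cmax_ratio,aucinf_ratio
saxagliptin,rat,iv_10mgkg,1.92,2.05,1.04
saxagliptin,rat,po_5mgkg,1.14,1.46,1.13
saxagliptin,human,po_2.5mg,1.32,1.22,0.96
saxagliptin,human,po_5mg_a,1.17,1.32,1.08
saxagliptin,human,po_5mg_b,1.60,1.15,0.73
nicardipine,rat,po_12mgkg,1.69,0.91,1.33
nicardipine,rat,po_15mgkg,2.08,0.68,0.85
nicardipine,human,po_20mg,1.92,0.72,1.50
nicardipine,human,po_40mg,1.66,0.63,0.86
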