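# Printed GMFE values per species x compound x parameter (computed in the source study
# from the per-study predicted/observed ratios in predobs_ratios.csv).
compound,species,parameter,gmfe
saxagliptin,rat,cmax,1.73
saxagliptin,rat,aucinf,1.08
saxagliptin,human,cmax,1.23
saxagliptin,human,aucinf,1.16
nicardipine,rat,cmax,1.27
nicardipine,rat,aucinf,1.15
nicardipine,human,cmax,1.48
nicardipine,human,aucinf,1.33
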