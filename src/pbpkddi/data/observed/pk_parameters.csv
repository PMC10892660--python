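# Printed PK parameter summaries used as evaluation inputs (means, SD where reported).
# role: observed = in-vivo/literature study; predicted = whole-body model point prediction.
# Parameter units are embedded in the parameter names: ng/mL (cmax), h (tmax, thalf),
# ng*h/mL (aucinf), L/h/kg (cl_f).
species,compound,study,role,parameter,value,sd
rat,saxagliptin,sxg_po_5mgkg,observed,cmax_ng_ml,98.5,15.1
rat,saxagliptin,sxg_po_5mgkg,observed,tmax_h,0.417,0.129
rat,saxagliptin,sxg_po_5mgkg,observed,thalf_h,1.82,0.737
rat,saxagliptin,sxg_po_5mgkg,observed,aucinf_ng_h_ml,157,23.1
rat,saxagliptin,sxg_po_5mgkg,observed,cl_f_l_h_kg,32.5,5.15
rat,saxagliptin,sxg_po_5mgkg_with_ncd,observed,cmax_ng_ml,281,147
rat,saxagliptin,sxg_po_5mgkg_with_ncd,observed,tmax_h,0.464,0.094
rat,saxagliptin,sxg_po_5mgkg_with_ncd,observed,thalf_h,2.97,1.23
rat,saxagliptin,sxg_po_5mgkg_with_ncd,observed,aucinf_ng_h_ml,408,213
rat,saxagliptin,sxg_po_5mgkg_with_ncd,observed,cl_f_l_h_kg,14.3,4.86
rat,nicardipine,ncd_po_15mgkg,observed,cmax_ng_ml,132,35.3
rat,nicardipine,ncd_po_15mgkg,observed,tmax_h,0.357,0.134
rat,nicardipine,ncd_po_15mgkg,observed,thalf_h,5.76,1.45
rat,nicardipine,ncd_po_15mgkg,observed,aucinf_ng_h_ml,408,121
rat,nicardipine,ncd_po_15mgkg,observed,cl_f_l_h_kg,39.7,11.9
rat,saxagliptin,sxg_po_5mgkg,predicted,cmax_ng_ml,144,
rat,saxagliptin,sxg_po_5mgkg,predicted,thalf_h,1.63,
rat,saxagliptin,sxg_po_5mgkg,predicted,aucinf_ng_h_ml,177,
human,saxagliptin,sxg_po_2.5mg,observed,cmax_ng_ml,7.89,
human,saxagliptin,sxg_po_2.5mg,observed,thalf_h,7.21,
human,saxagliptin,sxg_po_2.5mg,observed,aucinf_ng_h_ml,49.1,
human,saxagliptin,sxg_po_2.5mg,predicted,cmax_ng_ml,9.64,
human,saxagliptin,sxg_po_2.5mg,predicted,thalf_h,5.33,
human,saxagliptin,sxg_po_2.5mg,predicted,aucinf_ng_h_ml,46.9,
rat,nicardipine,ncd_po_15mgkg,predicted,cmax_ng_ml,69.3,
rat,nicardipine,ncd_po_15mgkg,predicted,thalf_h,2.96,
rat,nicardipine,ncd_po_15mgkg,predicted,aucinf_ng_h_ml,333,
human,nicardipine,ncd_po_40mg,observed,cmax_ng_ml,58.8,
human,nicardipine,ncd_po_40mg,observed,thalf_h,2.80,
human,nicardipine,ncd_po_40mg,observed,aucinf_ng_h_ml,163,
human,nicardipine,ncd_po_40mg,predicted,cmax_ng_ml,36.4,
human,nicardipine,ncd_po_40mg,predicted,thalf_h,3.44,
human,nicardipine,ncd_po_40mg,predicted,aucinf_ng_h_ml,138,
rat,saxagliptin,ddi_sxg_alone,predicted,cmax_ng_ml,147,
rat,saxagliptin,ddi_sxg_alone,predicted,aucinf_ng_h_ml,193,
rat,saxagliptin,ddi_sxg_with_ncd,predicted,cmax_ng_ml,395,
rat,saxagliptin,ddi_sxg_with_ncd,predicted,aucinf_ng_h_ml,490,
human,saxagliptin,ddi_sxg_alone,predicted,cmax_ng_ml,9.81,
human,saxagliptin,ddi_sxg_alone,predicted,aucinf_ng_h_ml,50.5,
human,saxagliptin,ddi_sxg_with_ncd,predicted,cmax_ng_ml,10.8,
human,saxagliptin,ddi_sxg_with_ncd,predicted,aucinf_ng_h_ml,52.9,
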