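strain_id,otu_id,clearance_specific,growth_high_light,growth_low_light,is_mixotroph
Florenciella_parvula,OTU_FlorP,0.30,0.48,0.00,True
Florenciella_sp,OTU_FlorX,0.60,0.55,0.12,True
Chrysochromulina_sp1,OTU_Chryso1,1.50,0.22,0.00,True
Chrysochromulina_sp2,OTU_Chryso2,2.20,0.22,0.00,True
Triparma_sp,OTU_Triparma,3.00,0.28,0.00,True
ChloraX,OTU_ChloraX,4.50,0.18,0.00,True
ChrysoH,OTU_ChrysoH,8.00,0.00,0.00,True
Ostreococcus_sp,OTU_Ostreo,0.00,0.38,0.25,False
Chloropicon_sp,OTU_Chloropicon,0.00,0.42,0.31,False
Micromonas_sp,OTU_Micromonas,0.00,0.46,0.35,False
Pelagomonas_sp,OTU_Pelago,0.00,0.52,0.42,False
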