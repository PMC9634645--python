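row_label,ecotype,year,Noctuidae,Coleophora,Coleoptera,Diptera_Delia,gall
Lom_Ca_2019,Ca,2019,7,0,0,0,0
Lom_Ca_2020,Ca,2020,2,0,0,0,0
Del_Ca_2019,Ca,2019,4,0,3,0,0
Sy_Ca_2020,Ca,2020,1,0,0,0,0
Coi_Ca_2020,Ca,2020,6,0,0,0,0
Nes_Si_2019,Si,2019,5,2,8,25,20
Nes_Si_2020,Si,2020,3,1,2,0,0
Rav_Si_2019,Si,2019,6,0,7,7,1
Rav_Si_2020,Si,2020,7,1,4,0,0
Tom_Si_2019,Si,2019,8,34,0,1,0
Tom_Si_2020,Si,2020,5,2,5,1,1
Ham_Si_2019,Si,2019,18,0,0,0,0
Ham_Si_2020,Si,2020,18,0,3,0,0
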