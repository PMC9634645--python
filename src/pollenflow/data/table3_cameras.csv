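valley,population_id,ecotype,date,duration_h,n_flowers_filmed,n_flowers_visited,n_moths
Viroin,Del_Ca,Ca,2019-06-01,7.25,34,1,1
Viroin,Lom_Ca,Ca,2019-05-31,2.17,40,1,1
Ourthe,Coi_Ca,Ca,2020-05-19,2.83,78,0,0
Ourthe,Coi_Ca,Ca,2020-05-20,2.83,58,4,2
Ourthe,Sy_Ca,Ca,2020-05-19,2.75,51,0,0
Ourthe,Sy_Ca,Ca,2020-05-20,4.58,85,16,7
Viroin,Nes_Si,Si,2019-05-31,7.67,28,0,1
Viroin,Rav_Si,Si,2019-06-01,7.5,15,12,7
Ourthe,Ham_Si,Si,2020-05-19,5.83,73,20,10
Ourthe,Ham_Si,Si,2020-05-20,2.67,35,10,6
Ourthe,Tom_Si,Si,2019-06-07,7.08,27,11,6
Ourthe,Tom_Si,Si,2020-05-19,2.75,69,0,0
Ourthe,Tom_Si,Si,2020-05-20,5.25,55,18,3
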