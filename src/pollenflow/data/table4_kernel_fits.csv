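valley,population,ecotype,morans_I,morans_significant,alpha,beta,delta_k_m,gamma,gamma_p
Viroin,Del_Ca,Ca,0.01,False,0.0001,0.20,18.1,-0.275,0.031
Viroin,Rav_Si,Si,0.10,False,28.9,0.83,87.7,-0.477,0.001
Viroin,Nes_Si,Si,-0.01,False,388.0,2.98,287.0,-0.393,0.001
Viroin,Lom_Ca,Ca,-0.01,False,0.0001,0.16,2642.0,-0.441,0.001
Ourthe,Coi_Ca,Ca,0.52,True,5.1,0.73,21.9,-0.456,0.001
Ourthe,Ham_Si,Si,-0.04,False,99.3,1.08,173.0,-0.347,0.005
Ourthe,Tom_Si,Si,0.05,False,,,,-0.011,0.923
Ourthe,Sy_Ca,Ca,0.23,True,1.8,0.39,160.0,-0.480,0.001
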