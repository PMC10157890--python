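enzyme,sequence,K_M_uM,K_M_sd,k_cat_s,k_cat_sd,efficiency_M_s,efficiency_sd
KDAC6,FRKacRW,70,30,0.07,0.007,970,260
KDAC6,FRKacAW,180,30,0.30,0.02,1600,700
KDAC6,FRKacWR,28,6,0.23,0.02,8300,2500
KDAC6,FRKacWA,28,6,0.32,0.02,11000,3000
KDAC6,FRKacAR,40,21,0.08,0.01,2100,600
KDAC6,FRKacRA,140,50,0.12,0.01,820,260
KDAC8,FRKacRW,500,50,0.230,0.007,470,150
KDAC8,FRKacAW,680,160,0.43,0.04,640,220
KDAC8,FRKacWR,154,40,0.110,0.005,650,130
KDAC8,FRKacWA,680,360,0.14,0.03,210,70
KDAC8,FRKacAR,400,260,0.020,0.003,41,13
KDAC8,FRKacRA,1900,250,0.080,0.005,44,20
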