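{
 "CLren_m1": 89.48858559638555,
 "CLren_m2": 250.0,
 "Km_gli2m1": 50.0,
 "Kp_gli": 0.11358411175638239,
 "MW_gli": 490.6,
 "MW_m1": 506.6,
 "MW_m2": 520.6,
 "Q_co": 180.0,
 "Q_gu": 32.4,
 "Q_ki": 34.2,
 "Q_li_art": 11.7,
 "V_ar": 1.2,
 "V_ki": 0.3,
 "V_li": 1.5,
 "V_re": 30.0,
 "V_ve": 1.8,
 "Vmax_gli2m1": 295.2323843716163,
 "bodyweight": 75.0,
 "f_absorption": 1.0,
 "f_cirrhosis": 0.0,
 "f_cyp2c9": 1.0,
 "f_renal_function": 1.0,
 "ftissue_gli": 1.0559903288415176,
 "k_abs": 0.8581456928226052,
 "k_diss": 1.1,
 "k_m12m2": 1.400000001943619,
 "k_sec_m1": 5.580104605972157,
 "k_sec_m2": 0.95,
 "ps_li_gli": 3.0477073382211475,
 "ps_li_m1": 10.0,
 "ps_li_m2": 10.0
}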