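{
 "f_ctp_c": 0.8661986781302478,
 "n_starts": 1,
 "seed": 42,
 "features": {
  "cmax_1mg": 85.69621798298589,
  "auc_8mg": 3987.559656246998,
  "urine48_8mg": 7.091115823461962,
  "tmax_4mg": 2.2767762049136366,
  "thalf_4mg": 4.000801978300644,
  "cmax_8mg_40kg": 1114.6394367712392,
  "clapp_m1_normal": 136.3114283818189,
  "clapp_m1_severe": 51.4592549916119,
  "auc_fold_cyp_0.23": 2.1475714689187884,
  "auc_fold_ctp_c": 3.5028780697817887,
  "cmax_ctp_c_1mg": 122.61609617018895
 },
 "per_start_cost": [
  0.03374000093580843,
  0.0017153605066154455,
  0.03545535379556756
 ]
}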