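{
 "cdi_coupling": 0.29999999999999705,
 "cdi_coupling_slow": 0.014592589001384866,
 "cdi_frac_fast": 0.20411030806223235,
 "frac_fast": 0.16794443044834556,
 "frac_persistent": 0.16054903236928814,
 "frac_slow": 0.6715065371823663,
 "g_max": 11.985004193844684,
 "hill_slope": 1.0,
 "ic50": 60.52251117644206,
 "name": "S652W_L",
 "q_on_total": 150.0,
 "rundown_rate": 3.0,
 "slope_act": 8.425200966236902,
 "slope_inact": 5.735079084916224,
 "tail_slow_frac": 0.2696629213483146,
 "tau_act_k": 46.54418514998593,
 "tau_act_max": 0.1944021283319707,
 "tau_act_v": -30.0,
 "tau_cdi_recovery": 26.80991513498878,
 "tau_cdi_recovery_slow": 3154.722908713638,
 "tau_fast_0": 63.20283563082373,
 "tau_q": 0.2,
 "tau_slow_0": 824.8467730620429,
 "tau_tail_slow": 1.12,
 "tau_v_dep": 79.35871240283205,
 "v_half_act": 3.9252830716726903,
 "v_half_inact": -13.095739319114706,
 "v_rev": 64.53634435684464,
 "v_tau_vdi": -10.0
}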