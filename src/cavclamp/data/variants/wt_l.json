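{
 "cdi_coupling": 0.29999999999999705,
 "cdi_coupling_slow": 0.014592589001384866,
 "cdi_frac_fast": 0.20411030806223235,
 "frac_fast": 0.10145990729035825,
 "frac_persistent": 0.21689342572038633,
 "frac_slow": 0.6816466669892555,
 "g_max": 9.954225142355579,
 "hill_slope": 1.0,
 "ic50": 61.07989953751415,
 "name": "WT_L",
 "q_on_total": 158.9,
 "rundown_rate": 3.0,
 "slope_act": 9.30473607221575,
 "slope_inact": 5.618704042323097,
 "tail_slow_frac": 0.2696629213483146,
 "tau_act_k": 46.54418514998593,
 "tau_act_max": 0.1944021283319707,
 "tau_act_v": -30.0,
 "tau_cdi_recovery": 26.80991513498878,
 "tau_cdi_recovery_slow": 3154.722908713638,
 "tau_fast_0": 5.000000000000001,
 "tau_q": 0.2,
 "tau_slow_0": 1224.187253532789,
 "tau_tail_slow": 1.12,
 "tau_v_dep": 79.99999039392866,
 "v_half_act": -0.7043338253851987,
 "v_half_inact": -25.704007902232334,
 "v_rev": 70.78164090639457,
 "v_tau_vdi": -10.0
}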