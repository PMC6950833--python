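{
 "cdi_coupling": 0.29999994882997777,
 "cdi_coupling_slow": 0.04534333661828199,
 "cdi_frac_fast": 0.6867766740153739,
 "frac_fast": 0.07744300796594385,
 "frac_persistent": 0.11418496384598058,
 "frac_slow": 0.8083720281880756,
 "g_max": 9.317391387119597,
 "hill_slope": 1.0,
 "ic50": 54.92382431559982,
 "name": "WT_S",
 "q_on_total": 150.0,
 "rundown_rate": 3.0,
 "slope_act": 7.03246220686833,
 "slope_inact": 4.754929286530781,
 "tail_slow_frac": 0.2696629213483146,
 "tau_act_k": 46.54418514998593,
 "tau_act_max": 0.1944021283319707,
 "tau_act_v": -30.0,
 "tau_cdi_recovery": 301.7308643118456,
 "tau_cdi_recovery_slow": 1609.5153664038648,
 "tau_fast_0": 80.81490815885924,
 "tau_q": 0.2,
 "tau_slow_0": 1210.8725120819615,
 "tau_tail_slow": 1.12,
 "tau_v_dep": 73.63987601382527,
 "v_half_act": -11.087090805752121,
 "v_half_inact": -31.207159270038076,
 "v_rev": 63.713261792292684,
 "v_tau_vdi": -10.0
}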