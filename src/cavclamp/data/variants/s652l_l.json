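{
 "cdi_coupling": 0.03377671857461902,
 "cdi_coupling_slow": 0.03378040396499275,
 "cdi_frac_fast": 0.5539177310674883,
 "frac_fast": 0.4184532240193563,
 "frac_persistent": 0.10952081799150978,
 "frac_slow": 0.4720259579891339,
 "g_max": 8.414074751994232,
 "hill_slope": 1.0,
 "ic50": 17.353612487186396,
 "name": "S652L_L",
 "q_on_total": 140.3,
 "rundown_rate": 3.0,
 "slope_act": 7.720067755530211,
 "slope_inact": 4.994538087941158,
 "tail_slow_frac": 0.6506024096385542,
 "tau_act_k": 21.2829557118897,
 "tau_act_max": 0.43384761149509626,
 "tau_act_v": -30.0,
 "tau_cdi_recovery": 2960.7288073335503,
 "tau_cdi_recovery_slow": 2961.625537928295,
 "tau_fast_0": 145.58334991790554,
 "tau_q": 0.2,
 "tau_slow_0": 1509.278703764594,
 "tau_tail_slow": 1.95,
 "tau_v_dep": 79.9999999999999,
 "v_half_act": -17.4869458498106,
 "v_half_inact": -43.25590846382428,
 "v_rev": 59.91463310857739,
 "v_tau_vdi": -10.0
}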