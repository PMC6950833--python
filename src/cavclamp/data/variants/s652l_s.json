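{
 "cdi_coupling": 0.27697445665736153,
 "cdi_coupling_slow": 0.041335010655302,
 "cdi_frac_fast": 0.725168236554552,
 "frac_fast": 0.570319741837561,
 "frac_persistent": 0.036574899543654754,
 "frac_slow": 0.3931053586187843,
 "g_max": 8.893718473486356,
 "hill_slope": 1.0,
 "ic50": 14.321028656302376,
 "name": "S652L_S",
 "q_on_total": 140.0,
 "rundown_rate": 3.0,
 "slope_act": 5.184729972162051,
 "slope_inact": 4.253721656110022,
 "tail_slow_frac": 0.6506024096385542,
 "tau_act_k": 21.2829557118897,
 "tau_act_max": 0.43384761149509626,
 "tau_act_v": -30.0,
 "tau_cdi_recovery": 4999.9999999999945,
 "tau_cdi_recovery_slow": 2102.802744468485,
 "tau_fast_0": 160.22287522674375,
 "tau_q": 0.2,
 "tau_slow_0": 2370.150294597677,
 "tau_tail_slow": 1.95,
 "tau_v_dep": 79.99999999275911,
 "v_half_act": -26.072998565085268,
 "v_half_inact": -47.12509013476781,
 "v_rev": 57.1590501252707,
 "v_tau_vdi": -10.0
}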