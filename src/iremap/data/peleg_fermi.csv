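n_pulses,t_p_us,e_c_kv_cm,k_kv_cm
8,100,2.344,0.2677
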