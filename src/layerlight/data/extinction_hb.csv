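wavelength_nm,eps_hbo2_cm1_M,eps_hb_cm1_M
660,319.6,3226.56
690,276.0,2051.96
750,518.0,1405.24
830,974.0,693.04
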