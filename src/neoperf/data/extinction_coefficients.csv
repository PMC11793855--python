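wavelength_nm,eps_hbo2,eps_hb,b_factor
700,0.290,1.7943,1.0
910,1.2162,0.7746,1.0
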