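face_size_mm,elements,outlet_pressure_mmhg,wss_pa
0.13-0.15,87000,105.516,6.31
0.12-0.15,176000,105.512,7.14
0.09-0.12,400000,105.483,7.78
0.07-0.09,657000,105.460,8.01
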