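face_size_mm,elements,outlet_pressure_mmhg,wss_pa
0.13,292000,105.494,6.38
0.10,540000,105.487,7.19
0.09,582000,105.458,7.85
0.07,1232000,105.443,8.14
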