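vessel,measured_mmhg,fsi_transient_mmhg,rigid_transient_mmhg,fsi_steady_mmhg,rigid_steady_mmhg
1-RCA,103.04,105.93,106.06,105.46,105.48
2-RCA,104.73,103.52,103.38,103.82,103.71
3-LAD,89.32,89.03,89,89.17,89.15
4-RCA,61.95,63.68,63.83,64.01,64.22
4-LAD,67.47,70.72,71.45,70.94,71.59
5-RCA,105.2,102.42,102.68,102.51,102.58
5-LAD,85.95,83.64,83.85,83.59,83.72
6-LAD,83.52,82.8,82.77,82.98,83.03
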