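vessel,measured_mmhg,p_vmax_mmhg,p_076vmax_mmhg,p_05vmax_mmhg
1-RCA,103.04,105.48,106.16,106.75
2-RCA,104.73,103.71,106.56,107.6
3-LAD,89.32,89.15,90.48,91.19
4-RCA,61.95,64.22,65.02,65.66
4-LAD,67.47,71.59,73.21,74.68
5-RCA,105.2,102.58,103.18,103.53
5-LAD,85.95,83.72,84.07,84.55
6-LAD,83.52,83.03,85.23,86.96
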