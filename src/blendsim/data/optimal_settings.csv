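filling_level,rotational_speed,blending_time,drug_content_pred,drug_content_exp,drug_content_abs_bias,cu_pred,cu_exp,cu_abs_bias
32,24,24,96.67,96.82,0.15,0.07,0.98,0.91
40,24,24,95.72,95.53,0.19,0.94,1.54,0.60
36,23,24,95.96,96.25,0.29,1.15,1.88,0.73
32,22,24,96.01,95.70,0.31,1.35,2.14,0.79
40,22,24,95.44,95.51,0.07,2.23,2.75,0.52
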