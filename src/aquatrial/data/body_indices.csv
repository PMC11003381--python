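diet,cf,cf_se,vsi,vsi_se,hsi,hsi_se,moisture,ash,crude_protein,crude_fat
Control,3.14,0.06,11.57,0.37,2.87,0.2,71.18,4.27,16.93,6.2
A33,3.3,0.1,13.06,0.54,4.3,0.47,70.74,4.4,16.73,6.39
A67,3.17,0.05,12.06,0.53,3.02,0.38,71.81,4.48,16.92,5.34
A100,3.14,0.07,12.2,0.36,2.98,0.17,71.64,4.45,16.79,5.67
B33,3.24,0.08,12.9,0.66,3.15,0.17,71.05,4.35,16.79,5.96
B67,3.24,0.07,13.09,0.64,3.52,0.35,71.39,4.38,16.79,5.72
B100,3.29,0.07,12.31,0.61,3.46,0.51,71.39,4.27,16.69,5.95
C33,3.34,0.07,12.43,0.52,3.47,0.35,71.24,4.24,16.2,6.4
C67,3.34,0.07,11.83,0.45,3.06,0.36,70.96,4.36,16.5,6.03
C100,3.33,0.06,13.2,0.56,3.19,0.55,71.44,4.39,17.15,5.52
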