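diet,ibw,ibw_se,sr,sr_se,fr,fr_se,fbw,fbw_se,sgr,sgr_se,fe,fe_se,per,per_se,pre,pre_se
Control,15.21,0.05,96.2,1.71,3.03,0.03,59.05,0.42,2.42,0.01,65.42,1.43,1.91,0.04,33.67,0.68
A33,15.15,0.07,96.67,1.71,2.94,0.03,61.38,0.68,2.5,0.02,69.74,0.82,2.06,0.02,35.54,0.46
A67,15.2,0.1,97.6,0.5,3.0,0.05,56.91,0.67,2.36,0.02,65.9,1.05,1.92,0.03,33.9,0.87
A100,15.18,0.1,96.2,2.06,3.06,0.03,53.68,1.02,2.25,0.04,61.79,0.99,1.81,0.03,31.52,0.41
B33,15.2,0.06,95.23,3.42,2.98,0.04,60.53,0.6,2.47,0.01,67.15,0.86,1.95,0.03,34.76,0.71
B67,15.23,0.12,96.67,1.26,2.95,0.02,60.21,0.81,2.45,0.02,68.3,1.3,1.99,0.04,35.52,0.49
B100,15.15,0.08,96.67,1.71,2.94,0.03,61.81,1.07,2.51,0.03,69.75,0.85,2.06,0.03,36.33,0.24
C33,15.07,0.05,95.7,2.48,2.95,0.04,60.25,0.7,2.48,0.02,68.23,1.96,2.0,0.06,34.14,0.5
C67,15.2,0.03,95.7,0.81,2.94,0.05,58.98,0.66,2.42,0.02,67.61,1.11,1.99,0.03,34.44,0.2
C100,15.26,0.04,96.67,0.97,2.97,0.02,59.05,0.41,2.42,0.01,66.82,0.64,1.98,0.02,35.25,0.36
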