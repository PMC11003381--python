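amino_acid,Control,A33,A67,A100,B33,B67,B100,C33,C67,C100
lysine,2.16,2.15,2.20,2.26,2.20,2.18,2.23,2.13,2.10,2.11
methionine,0.56,0.62,0.59,0.57,0.57,0.56,0.58,0.54,0.52,0.49
threonine,1.31,1.32,1.35,1.35,1.35,1.34,1.34,1.32,1.31,1.33
arginine,1.96,1.96,1.97,2.07,1.92,1.98,2.05,1.99,2.00,2.08
leucine,2.49,2.45,2.46,2.45,2.53,2.55,2.55,2.48,2.43,2.51
isoleucine,1.46,1.48,1.47,1.45,1.43,1.49,1.46,1.41,1.41,1.49
valine,1.55,1.54,1.52,1.53,1.59,1.58,1.55,1.51,1.55,1.60
phenylalanine,1.48,1.51,1.45,1.49,1.57,1.50,1.52,1.45,1.47,1.57
histidine,0.69,0.69,0.76,0.73,0.73,0.74,0.63,0.81,0.73,0.76
asparagine,2.77,2.73,2.76,2.73,2.83,2.76,2.82,2.83,2.77,2.84
serine,1.29,1.33,1.36,1.31,1.31,1.31,1.35,1.34,1.33,1.32
glutamic acid,5.57,5.58,5.55,5.61,5.54,5.54,5.68,5.60,5.60,5.65
glycine,1.45,1.43,1.46,1.47,1.47,1.43,1.42,1.51,1.51,1.45
alanine,1.57,1.60,1.63,1.63,1.56,1.59,1.61,1.61,1.62,1.58
tyrosine,0.99,1.05,1.06,1.00,1.00,1.02,1.03,1.01,0.97,1.04
proline,1.55,1.65,1.62,1.56,1.69,1.67,1.98,1.67,1.59,1.74
cysteine,2.21,1.71,1.71,2.09,1.61,1.79,1.71,1.71,1.90,2.12
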