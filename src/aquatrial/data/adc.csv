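substance,Control,A33,A67,A100,B33,B67,B100,C33,C67,C100
dry matter,55.96,57.46,49.75,49.40,52.53,55.10,58.88,58.80,55.87,54.05
gross energy,61.15,62.16,53.46,53.73,56.95,57.41,60.09,62.66,59.06,54.17
crude protein,78.01,82.68,76.06,72.50,79.35,79.38,82.25,79.45,78.40,79.19
total essential amino acid,84.58,86.70,83.37,82.93,85.24,86.79,87.60,85.31,86.37,85.44
total nonessential amino acid,83.15,85.13,82.29,78.61,82.88,84.86,87.69,83.22,85.62,84.63
lysine,84.20,86.74,84.10,83.16,85.55,85.58,86.70,84.39,85.12,83.96
methionine,97.08,97.79,97.07,96.79,97.57,97.75,98.24,97.54,97.70,97.79
threonine,75.19,77.77,75.61,71.68,76.84,77.44,78.92,76.11,76.53,76.62
arginine,76.74,76.11,71.15,72.69,72.44,80.88,78.84,76.26,79.05,75.10
leucine,82.75,85.81,82.21,81.36,83.93,85.27,86.97,84.38,85.26,84.52
isoleucine,82.32,86.94,83.39,82.48,84.76,84.66,85.77,85.24,84.46,85.62
valine,79.69,83.02,75.74,75.27,81.01,82.53,83.30,78.87,82.02,82.31
phenylalanine,82.31,84.66,77.41,79.99,82.68,84.65,87.65,81.17,84.34,83.51
histidine,84.11,86.78,87.24,84.28,86.90,87.72,88.18,89.20,87.60,88.24
asparagine,82.13,85.21,81.64,78.28,83.80,84.37,87.38,83.78,84.33,85.03
serine,80.37,83.49,82.60,79.23,83.07,82.68,84.33,83.22,82.58,83.76
glutamic acid,88.21,89.75,87.26,85.87,88.56,89.52,91.45,88.67,89.88,89.33
glycine,73.59,76.92,76.23,68.22,75.18,79.08,84.62,76.64,80.83,79.02
alanine,80.33,81.51,82.08,74.72,80.54,81.73,85.84,81.97,82.56,82.93
tyrosine,83.77,86.64,84.58,80.43,83.85,86.51,86.83,84.10,85.69,85.51
proline,77.77,80.80,74.25,72.32,79.05,82.35,88.02,79.00,82.26,80.24
cysteine,85.11,84.80,78.65,73.15,74.65,81.62,82.73,74.79,86.23,79.86
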