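component,Control,A33,A67,A100,B33,B67,B100,C33,C67,C100
crude protein,34.27,33.81,34.29,34.18,34.36,34.23,34.01,34.09,33.94,33.48
crude fat,7.99,7.17,7.69,7.81,6.88,7.62,6.82,7.34,6.75,7.25
ash,10.58,9.69,8.83,9.52,8.5,8.78,8.43,9.66,9.11,8.76
gross energy (MJ/kg),18.02,18.23,18.41,18.46,18.39,18.21,18.28,18.38,18.53,17.94
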