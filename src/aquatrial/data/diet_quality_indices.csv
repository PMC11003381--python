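index,Control,A33,A67,A100,B33,B67,B100,C33,C67,C100
EAAI,95.83,97.07,97.52,97.71,97.78,97.86,97.50,96.34,94.86,97.26
DEAAI,79.07,82.39,79.22,78.71,81.42,83.19,83.75,80.39,80.15,81.66
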