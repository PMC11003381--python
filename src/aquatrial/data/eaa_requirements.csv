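amino_acid,requirement,source
lysine,3.30,Zhou et al.
methionine,0.89,Jia et al.
threonine,1.70,Li
arginine,1.50,Tu et al.
leucine,1.80,Li
isoleucine,1.30,Li
valine,1.70,Li
phenylalanine,1.10,Ma
histidine,0.80,Ma
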