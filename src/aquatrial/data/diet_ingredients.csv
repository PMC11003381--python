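ingredient,Control,A33,A67,A100,B33,B67,B100,C33,C67,C100
fish meal,15.00,10.00,5.00,0.00,10.00,5.00,0.00,10.00,5.00,0.00
T. molitor meal,0.00,0.38,0.76,1.14,0.40,0.80,1.20,0.42,0.84,1.26
Chlorella meal,0.00,0.38,0.76,1.14,0.40,0.80,1.20,0.42,0.84,1.26
Clostridium autoethanogenum protein,0.00,3.04,6.08,9.12,2.40,4.80,7.20,1.68,3.36,5.04
cottonseed protein concentrate,0.00,0.76,1.52,2.28,1.60,3.20,4.80,2.52,5.04,7.56
rapeseed meal,25.00,25.00,25.00,25.00,25.00,25.00,25.00,25.00,25.00,25.00
soybean meal,26.00,26.00,26.00,26.00,26.00,26.00,26.00,26.00,26.00,26.00
corn starch,15.00,15.00,15.00,15.00,15.00,15.00,15.00,15.00,15.00,15.00
microcrystalline cellulose,4.38,4.42,4.56,4.70,4.18,4.08,3.98,3.94,3.60,3.26
fish oil,3.00,3.20,3.35,3.50,3.20,3.35,3.50,3.20,3.35,3.50
soybean oil,3.00,3.20,3.35,3.50,3.20,3.35,3.50,3.20,3.35,3.50
mineral premix,5.00,5.00,5.00,5.00,5.00,5.00,5.00,5.00,5.00,5.00
vitamin premix,0.39,0.39,0.39,0.39,0.39,0.39,0.39,0.39,0.39,0.39
sodium benzoate,0.02,0.02,0.02,0.02,0.02,0.02,0.02,0.02,0.02,0.02
sodium carboxymethyl cellulose,3.00,3.00,3.00,3.00,3.00,3.00,3.00,3.00,3.00,3.00
choline chloride,0.11,0.11,0.11,0.11,0.11,0.11,0.11,0.11,0.11,0.11
yttrium trioxide,0.10,0.10,0.10,0.10,0.10,0.10,0.10,0.10,0.10,0.10
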