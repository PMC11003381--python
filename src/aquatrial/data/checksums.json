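{
 "diet_amino_acids.csv": "fb2300676e724130f22bd44353e27c3d090f71514e3187dd29352b46d55d58d9",
 "eaa_requirements.csv": "1048a9aed3e96dadabce86320892e6585f7c0b07a3a35ea7fab1f80fe5260387",
 "diet_ingredients.csv": "2b5818478706aea8c9e8e9f9f48a02016a41a26c7c2da4cb7c2cdaa535bcd988",
 "diet_proximate.csv": "aa81ccf52bbae239c1b39546dea81e05201e1504f72289cd05233dfe51fa7642",
 "diet_quality_indices.csv": "9e9cafc09c29013e33b3cdefebab40629e90685c8f41a9043ee7646c08919e58",
 "growth_performance.csv": "2cce2e2f58dad07e23c20531926337eb65e6105292b9fe3863be09c0ec1d509d",
 "body_indices.csv": "5a0aa88da3c92f1f82bd5add1596424a1215d520ce6ca780171a9637983ee68a",
 "adc.csv": "738683738cdaab4e2c87286b54ab76eec351a64bd6f77d35518e0e14c0fe1105"
}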