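condition,I,II,II',III,IV,V,VI,VII,other
AMBER-KK,97.8,0.0,0.0,0.0,0.0,0.0,0.0,0.0,2.2
AMBER-KWK,43.2,11.0,4.6,16.6,8.5,0.4,13.3,0.0,2.4
CHARMM-KK,52.3,0.7,0.3,7.1,4.0,0.2,10.3,7.6,17.5
CHARMM-KWK,2.7,35.5,11.6,0.0,0.0,4.8,0.0,0.7,44.7
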