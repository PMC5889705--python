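map_class,P,S,C,NAP,mapped_area
P,522,0,14,0,5395
S,24,619,119,2,12309
C,50,0,348,7,8206
NAP,0,0,20,418,5913
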