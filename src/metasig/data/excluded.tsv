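name
ebv-miR-BART1-5p
ebv-miR-BART2-5p
kshv-miR-K12-1-5p
hcmv-miR-UL112-3p
RNU6B
RNU44
U6-snRNA
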