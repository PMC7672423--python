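# Gel-shift regime: 1-h activation of the SI-gRNA before the dCas9 binding endpoint
# (dCas9 1 uM and dsDNA 100 nM are added at the endpoint, not integrated)
T: 2 uM
H1: 2 uM
H2: 2 uM
SIgRNA: 1 uM
t_end: 1 h
temperature_c: 37
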