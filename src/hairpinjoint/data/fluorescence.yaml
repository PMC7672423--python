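# Reporter assay regime: trigger + hairpins + RepF:RepQ duplex, 20-min endpoint at 37 C
T: 60 nM
H1: 60 nM
H2: 60 nM
RepFQ: 30 nM
t_end: 20 min
temperature_c: 37
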