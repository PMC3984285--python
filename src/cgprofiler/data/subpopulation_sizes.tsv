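subpopulation	n_individuals
African	43
African-European	46
CentralAsian	50
EastAsian	62
European	331
Hispanic	118
Other	31
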