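marker	haplotype_label	species
rpl32-trnL	A	aquatilis
rpl32-trnL	A	fluitans
rpl32-trnL	C	kauffmannii
rpl32-trnL	D	kauffmannii
rpl32-trnL	D	aquatilis
rpl32-trnL	I	circinatus
petL-psbE	A	aquatilis
petL-psbE	A	fluitans
petL-psbE	C	kauffmannii
petL-psbE	C	trichophyllus
petL-psbE	C	aquatilis
petL-psbE	F	circinatus
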