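region	locality	n_species_individuals	n_hybrid_individuals
Lithuania	L01	3	3
Lithuania	L02	3	0
Lithuania	L03	3	0
Lithuania	L04	3	0
Lithuania	L05	3	0
Lithuania	L06	3	0
Lithuania	L07	0	3
Lithuania	L08	0	3
Lithuania	L09	0	3
Lithuania	L10	0	3
Lithuania	L11	0	3
Lithuania	L12	0	3
Lithuania	L13	0	3
Lithuania	L14	0	3
Lithuania	L15	0	3
Lithuania	L16	0	3
Lithuania	L17	0	3
Lithuania	L18	0	3
Lithuania	L19	0	3
Lithuania	L20	0	3
Lithuania	L21	0	3
Central European Russia	R01	2	3
Central European Russia	R02	2	2
Central European Russia	R03	2	2
Central European Russia	R04	0	2
Central European Russia	R05	0	2
Central European Russia	R06	0	2
Central European Russia	R07	2	0
Central European Russia	R08	2	0
Central European Russia	R09	2	0
Central European Russia	R10	2	0
Central European Russia	R11	1	0
Central European Russia	R12	1	0
Central European Russia	R13	1	0
Central European Russia	R14	1	0
Central European Russia	R15	1	0
Central European Russia	R16	1	0
Central European Russia	R17	1	0
Central European Russia	R18	1	0
Central European Russia	R19	1	0
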