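isolate	line	position	change	coverage_low	coverage_high	frequency_low	frequency_high	p_value	support	feature	effect
AF16	MA3	12473	-N(870)	261	299	0.651	0.739	6.2e-291	209	Psi-nad5-2..nduo-5	Alternative Start Codon, Truncation
AF16	MA12	12479	-N(870)	233	260	0.823	0.918	0	214	Psi-nad5-2..nduo-5	Alternative Start Codon, Truncation
AF16	MA13	12479	-N(870)	167	188	0.793	0.892	1.2e-228	149	Psi-nad5-2..nduo-5	Alternative Start Codon, Truncation
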