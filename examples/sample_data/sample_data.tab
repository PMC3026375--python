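Genotyping project export
Any text may appear here before the sentinel line.
[DATA]	sample IDs
	1	2	3	4	5	6	7	8
SNP1	AA	AA	AA	AA	AA	AG	GG	GG
SNP2	AA	AA	AA	AA	AA	AT	AA	AA
SNP3	CC	CC	CT	CC	CC	CC	CC	CC
SNP4	GG	GG	GG	GG	GG	AG	--	--
SNP5	GG	GG	GG	GG	GG	AG	AG	AG
SNP6	AA	AA	--	--	--	AC	CC	CC
SNP7	AA	AA	AA	AA	AA	AG	TT	TT
SNP8	TT	GG	CC	CC	CC	CC	CC	CC
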