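PZA01271.1	1	0
PZA03613.1	1	9
PZA02129.1	1	37
PZA02032.1	1	51
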