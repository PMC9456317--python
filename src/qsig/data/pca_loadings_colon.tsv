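sample	PC1	PC2	PC3	PC4
plus1	-0.317	0.156	-0.272	0.336
plus2	-0.317	0.065	-0.151	0.255
plus3	-0.317	0.100	-0.221	0.166
plus4	-0.316	-0.038	0.694	0.478
plus5	-0.314	-0.799	-0.040	0.087
minus1	-0.316	0.347	0.353	-0.396
minus2	-0.317	0.143	-0.363	-0.013
minus3	-0.317	0.121	-0.262	-0.157
minus4	-0.317	0.233	0.208	-0.163
minus5	-0.316	-0.336	0.057	-0.591
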