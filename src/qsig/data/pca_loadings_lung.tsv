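sample	PC1	PC2	PC3	PC4
p136.1	0.273	0.364	0.300	0.053
p136.2	0.230	0.495	0.224	-0.037
p136.3	0.275	0.364	0.275	0.068
m136.1	0.305	-0.040	-0.225	0.358
m136.2	0.213	0.298	-0.600	-0.689
m136.3	0.246	0.268	-0.462	0.531
p229.1	0.320	-0.200	0.178	-0.160
p229.2	0.318	-0.178	0.226	-0.166
p229.3	0.316	-0.159	0.201	-0.140
m229.1	0.318	-0.285	-0.176	0.133
m229.2	0.325	-0.307	-0.052	0.068
m229.3	0.296	-0.235	-0.064	-0.113
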