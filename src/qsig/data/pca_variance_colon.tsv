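component	eigenvalue
1	9.874
2	0.042
3	0.025
4	0.015
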