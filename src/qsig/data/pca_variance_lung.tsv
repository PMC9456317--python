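component	eigenvalue
1	5.970
2	1.154
3	0.906
4	0.599
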