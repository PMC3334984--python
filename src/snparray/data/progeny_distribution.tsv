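n_progenies	n_snps
0	3
1	14
2	10
3	17
4	10
5	1
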