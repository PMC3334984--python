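chromosome	stage2_snps	array_snps	polymorphic_snps
1	5573	1114	919
2	7205	1396	1193
3	4031	811	680
4	8149	1619	1391
5	2692	546	459
6	4674	933	802
7	3943	793	668
8	4527	913	743
unanchored	1006	19	14
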