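parameter	value	total	failed	monomorphic	polymorphic
genic_location	exonic	30	4	3	23
genic_location	intronic	19	4	1	14
genic_location	utr	16	4	4	8
genic_location	intergenic	31	11	10	10
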