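key	value
stage1_pools_1_5	943549
stage1_pools_6_11	57933
stage1_pools_6_12	78805
stage2_genic	86360
stage2_exonic	41800
stage2_unanchored	1006
array_slots	9000
prevalidated_pinned	387
manufacturing_dropout	856
shared_polymorphic	5967
eu_only_polymorphic	425
us_only_polymorphic	477
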