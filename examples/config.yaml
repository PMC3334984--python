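# Flat key-value configuration for the snparray CLI.
# Keys matching SimConfig fields drive the synthetic study; everything is
# optional and defaults to the toy-scale study described in docs/methods.md.
seed: 42
n_chromosomes: 8
chromosome_length: 200000
n_unanchored: 2
unanchored_length: 50000
n_snps: 1500
n_accessions: 56
gene_density: 0.30
repeat_fraction: 0.05
error_rate: 0.01
failure_fraction: 0.05
nocall_rate: 0.02
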