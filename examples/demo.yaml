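# Demo pipeline configuration: a small allopolyploid complex that runs
# end-to-end in a few minutes on one CPU.
seed: 11
outdir: dupevo_demo
log_level: INFO

simulate:
  n_ancestral_genes: 150
  n_scaffolds: 2
  fractionation_prob: 0.2
  fractionation_bias: 0.6
  n_meth_replicates: 2
  n_dmg: 3

methylome:
  contexts: [CG]
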