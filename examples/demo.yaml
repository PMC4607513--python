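# Small end-to-end demonstration run (seconds on one CPU).
outdir: demo_run
simulate:
  seed: 7
  contigs:
    chr1:
      - [intergenic, 40000]
      - [intronic, 10000]
      - [exonic, 6000]
      - [intronic, 10000]
      - [intergenic, 40000]
  ancestral_count: 1500
  n_strains: 8
  filial_generations: 25
analyses:
  - canonical_class: AG
    compartment: intergenic
bootstrap_reps: 500
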