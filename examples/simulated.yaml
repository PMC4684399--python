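# End-to-end run on a synthetic cohort at the default study conditions.
seed: 1
flank_bp: 30
simulate:
  n_genes: 40
  cnv_events:
    - {gene: SIMG005, log2: 2.5}
    - {gene: SIMG020, log2: -3.0}
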