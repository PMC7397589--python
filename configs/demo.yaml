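# Demo pipeline configuration: full analysis on the default simulated
# 2 x 2 Mb genome.  Run with `loopspread run --config configs/demo.yaml`.
seed: 7
outdir: loopspread_demo
stages: [simulate, domains, spreading, hic-lri, gsea]
calling:
  fdr: 0.05
  n_swaps: 2
gsea:
  n_perm: 1000
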