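genome:
  synthetic:
    n_chroms: 1
    chrom_length: 100000
    base_composition:
    - 0.31
    - 0.19
    - 0.19
    - 0.31
    planted_motifs:
    - motif: GGTGT
      count: 5
      region: telomere_start
    - motif: GGTGT
      count: 5
      region: telomere_end
    - motif: GGTGT
      count: 3
      region: telomere_start
      double_gap:
      - 0
      - 3
    - motif: GGTGT
      count: 3
      region: telomere_end
      double_gap:
      - 0
      - 3
    - motif: GGTGT
      count: 20
      region: uniform
    telomere_window: 2000
    cpg_islands: []
    cpg_depletion: 0.0
    chrom_prefix: chr
  seed: 7
model:
  kind: sir
  variant: 2
abundances:
  RAP1: 4
  Sir3p: 4
  Sir3.spreader: 4
n_cycles: 50
snapshot_every: 10
seed: 1
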