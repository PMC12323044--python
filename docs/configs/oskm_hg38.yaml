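# Full-scale OSKM-vs-CpG-island-repressor model on the human reference
# genome.  Supply your own hg38 FASTA (and, for TSS summaries, a BED4 of
# one TSS per gene, e.g. derived from MANE-select transcripts); nothing
# is downloaded automatically.  Sweep `statewidth` (e.g. 200, 2000,
# 20000, 50000) across runs to reproduce the activation/repression
# trade-off; expect hours per run at this scale.
genome:
  fasta: hg38.fa
model:
  kind: oskm
  statewidth: 20000
n_cycles: 100
snapshot_every: 10
seed: 1
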