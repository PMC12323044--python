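# Full-scale SIR spreading model (Model 2: gapped double-motif seeding)
# on the S. cerevisiae reference genome.  Supply your own sacCer3 FASTA;
# it is never downloaded automatically.  For Model 1 set variant: 1.
genome:
  fasta: sacCer3.fa
model:
  kind: sir
  variant: 2
# abundances default to 500 per factor (sized for the ~12 Mb genome);
# override here if desired, e.g.  abundances: {RAP1: 800}
n_cycles: 200
snapshot_every: 10
seed: 1
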