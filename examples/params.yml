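# Example replication-cycle parameters for the gene-dosage model.
# C and D depend on strain and growth condition; these are plausible
# EXAMPLE values for E. coli K-12 at moderate growth, not defaults --
# supply your own measured or literature values.
replication:
  C_min: 42.0   # chromosome replication time, minutes
  D_min: 23.0   # termination-to-division time, minutes
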