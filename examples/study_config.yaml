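# Batch MR study configuration (paths are relative to where you run mrkit).
# Generate the referenced synthetic inputs first, e.g.:
#   mrkit simulate --seed 1 --k 100 --mediation --out data/

exposures:
  adiposity: data/exposure.tsv
  hdl_like: data/mediator.tsv

outcome_name: ear_disease
outcome_path: data/outcome.tsv

direction: both                 # forward | reverse | both
ladder: [5.0e-8, 5.0e-6, 5.0e-5]
reverse_ladder: [5.0e-6, 5.0e-5]
reverse_ladder_overrides:       # per-trait relaxation when instruments are scarce
  hdl_like: [5.0e-5]

min_snps: 3
clump_window_bp: 10000000
clump_r2: 0.001
# ld_path: data/ld_sparse.tsv   # optional; omit for distance-only clumping
# ld_format: sparse             # sparse (snp_a, snp_b, r2) | dense labelled matrix

n_boot: 1000
seed: 42
effects_model: multiplicative_random

mvmr_groups:
  lipids: [adiposity, hdl_like]

mediation_pairs:
  - [adiposity, hdl_like]

outdir: mr_results
fdr_column: true
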