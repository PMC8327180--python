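# One-arm simulation config for `bcrtrace simulate --config ... --out dir/`
# (the `bcrtrace run --demo` pipeline uses the built-in two-arm study).
germline:
  n_v: 19
  n_j: 4
  seed: 7
n_mice: 2
condition: treated
seed: 1
seq_error_rate: 0.001
sharing_dominance: 0.015
sharing_matrix:
  tumor:
    blood: 0.08
tissues:
  - name: tumor
    n_clones: 300
    clone_size_zipf_exponent: 2.0
    n_reads: 15000
    isotype_probs: {IGHM: 0.75, IGHG1: 0.06, IGHG2A: 0.08, IGHG2B: 0.06, IGHG3: 0.05}
    shm_model:
      IGHM: {weight: 0.5, mean_low: 2.0, mean_high: 12.0}   # bimodal tumor IgM
      IGHG1: 12.0
      IGHG2A: 12.0
      IGHG2B: 12.0
      IGHG3: 12.0
  - name: blood
    n_clones: 900
    clone_size_zipf_exponent: 1.1
    n_reads: 15000
    isotype_probs: {IGHM: 0.96, IGHG1: 0.01, IGHG2A: 0.01, IGHG2B: 0.01, IGHG3: 0.01}
    shm_model:
      IGHM: 1.5
      IGHG1: 6.0
      IGHG2A: 6.0
      IGHG2B: 6.0
      IGHG3: 6.0
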