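# Demonstration configuration: a small ground-truthed community with one
# phase-divergence-coupled genus, run end to end in under a minute.
# All thresholds are the study defaults; only simulation size and Monte
# Carlo effort are reduced.
seed: 123
n_rand: 199
rank_n_iter: 50
rank_min_asvs: 5
min_close_asvs: 4
gap_n_ref: 25
gap_k_max: 4
rho_n_perm: 25
simulate:
  n_genera: 6
  asvs_per_genus: 6
  reads_per_sample: 10000
  coupled_genera: 1
  phase_rate_per_sub: 8.0
  n_crt: 2
  n_years: 11
  seed: 123
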