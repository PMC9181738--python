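# Example end-to-end run on a synthetic registry with one deviant center.
outdir: dualbench_run
seed: 42
synthetic:
  n_centers: 6
  patients_per_center: 800
  center_intraop_shift:
    C02: 0.40
completeness_threshold: 0.10
split_fraction: 0.85
bootstrap_B: 500
stratified_bootstrap: false
subgroups: null   # null = all built-in urgency/procedure subgroups
log_level: INFO
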