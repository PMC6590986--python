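# Reduced demo configuration: full pipeline in under a minute on one CPU.
#   phasekeeper run --config configs/demo.yaml
seed: 1
outdir: artifacts_demo

noise:
  n_replicates: 4
  duration_min: 10

protocol:
  n_replicates: 2
  n_cycles: 10
  n_keep: 3

stats:
  phi_c: 0.34
  phi_c_grid: [0.2, 0.8, 31]
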