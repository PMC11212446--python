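# Example configuration for `noisytab sweep` / `noisytab ablate`.
# Omitted keys fall back to the package defaults described in docs/methods.md.

cohort:
  n_samples: 6000
  n_features: 20
  prevalence: 0.05
  separation: 1.0
  correlation: 0.3
  missing_rate: 0.05

mlp:
  hidden_sizes: [32, 32]
  learning_rate: 0.001
  batch_size: 256
  n_epochs: 60

ncr:
  k: 10
  weight: 1.0
  warmup_epochs: 30
  divergence: kl

mixup:
  alpha_beta: 0.4
  p_apply: 0.5

smoothing:
  epsilon: 0.1

sweep:
  noise_levels: [0.0, 0.1, 0.2, 0.3, 0.4]
  fp_rate: 0.005
  methods: [baseline, smoothing, mixup, ncr, mixup+ncr, gbt]
  n_seeds: 5
  target_sensitivity: 0.85
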