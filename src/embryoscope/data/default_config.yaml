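# Default experiment configuration. Seeds are mandatory everywhere:
# an absent seed is a validation error, never an implicit default.
stimulus:
  n_embryos: 400
  n_vertices: 1474
  axes: [2, 3]
  target_dprime: 2.5
  within_variance: 1.0
  seed: 101
roster:
  - subject_id: S1
    role: server
    learning_rate: 0.08
    perceptual_noise_sd: 0.3
  - subject_id: C1
    role: client
    expertise: naive
    compliance_weight: 0.6
    explanation_weight: 0.8
    conformity_bias: 15.0
    rating_noise_sd: 10.0
protocol:
  block_size: 40
  criterion_dprime: 1.68
  criterion_run_length: 3
  max_blocks: 60
  pre_test_blocks: 2
  post_test_blocks: 2
  n_server_trials: 1000
  scramble_mode: none
  provided_decisions: true
  provided_explanations: true
  perceived_source: expert
  seed: 202
output:
  out_dir: runs
  image_format: png
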