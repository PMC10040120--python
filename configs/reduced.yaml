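# reduced-scale profile: quick full-pipeline run (~1 min on one CPU)
generator:
  truth:
    n_respondents: 2000
  design:
    validation_fraction: 0.15
methods: [calibration, mice-parametric, mice-rf]
m: 5
n_iterations: 10
n_trees: 20
seed: 2018
output_dir: results/reduced
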