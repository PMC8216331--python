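# Demo configuration: a reduced synthetic study that runs end-to-end in
# seconds on one CPU while keeping every symptom above the 12-tweets/day
# exclusion threshold.  All keys can be overridden on the command line:
#
#   depsym all --config examples/demo.yaml --seed 1 --outdir runs/demo
synth:
  n_respondents: 3000
  n_users: 40000
  rng_seed: 2020
tau: 0.4
k: 25
exclusion_threshold: 12.0
lags: [-4, 4]
outdir: runs/demo
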