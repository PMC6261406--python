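# End-to-end demo: simulate the default array-screen cohort and analyze it.
schema_version: 1
out_dir: scratch/demo_run
seed: 1
ancestry_component: afr
simulation:
  n_cases: 23
  n_controls: 110
  seed: 1
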