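# Synthetic three-category study: KP/PFP/PLP-analog families whose N/Q-rich
# domains evolve at rate multipliers 3/2/1 across a nested genus/WGD/class
# species design.  Run with:  prioncons run-all --config examples/synthetic.yaml
output_dir: scratch/synthetic_out
seed: 11
simulate:
  n_per_category: 10     # families per category
  n_class: 8             # species counts are cumulative: genus ⊆ wgd ⊆ class
  n_wgd: 4
  n_genus: 2
params:
  evalue_max: 0.001
  core_length: 60
  schemes: [PC, BS]
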