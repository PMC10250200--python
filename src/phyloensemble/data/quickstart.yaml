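# Quickstart pipeline config: small synthetic scenario, light ensemble.
seed: 7
preset: Grp_1
output_dir: quickstart_out
scenario:
  n_species: 8
  n_strains: 12
  n_lakes: 4
ensemble:
  n_trees: 20
  noise_sd: 0.05
  iterations_per_tree: 60
  burn_in_per_tree: 40
  thin: 2
  tree_burn_in: 2
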