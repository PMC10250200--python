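# Declarative model presets for the comparative analyses.
# Each preset names columns of the prepared observation / lake tables
# (see phyloensemble.presets.prepare_observation_table / prepare_lake_table).
# "random_experiment" expands to phylogeny-over-strains + strain + lake terms;
# "random_lake" to a phylogeny-over-genera term.

Grp_1:
  kind: model
  dataset: experiment
  family: binomial-logit
  response: [n_group_cells, n_nongroup]
  fixed_terms:
    - {factor: predation}
    - {factor: nitrate}
    - {factor: turbulence}
  random: random_experiment

GR_1:
  kind: model
  dataset: experiment
  family: gaussian
  response: sgr
  fixed_terms:
    - {factor: predation}
    - {factor: nitrate}
    - {factor: turbulence}
    - {factor: group_present}
    - {covariate: prop_group, transform: logit, denominator: n_classified,
       at: {factor: group_present, level: yes}}
  random: random_experiment

RelGR_1:
  kind: model
  dataset: experiment
  family: gaussian
  response: rel_sgr
  fixed_terms:
    - {factor: predation}
    - {factor: nitrate}
    - {factor: turbulence}
    - {factor: group_present}
    - {covariate: prop_group, transform: logit, denominator: n_classified,
       at: {factor: group_present, level: yes}}
  random: random_experiment

GrazGR_1:
  kind: model
  dataset: experiment2
  family: gaussian
  response: sgr
  fixed_terms:
    - {factor: predation}
    - {factor: group_present}
    - {covariate: prop_group, transform: logit, denominator: n_classified,
       at: {factor: group_present, level: yes}}
  random: random_experiment

PredGR_1:
  kind: model
  dataset: experiment2
  family: gaussian
  response: pred_sgr
  fixed_terms:
    - {factor: predation}
    - {factor: group_present}
    - {covariate: prop_group, transform: logit, denominator: n_classified,
       at: {factor: group_present, level: yes}}
  random: random_experiment
  filters:
    - {drop_level: {factor: predation, level: none}}

SP_1:
  kind: model
  dataset: experiment
  family: binomial-logit
  response: [n_group_cells, n_nongroup]
  fixed_terms:
    - {factor: predation}
    - {factor: nitrate}
    - {factor: turbulence}
    - {covariate: prop_palmelloid, transform: logit, denominator: n_classified}
  random: random_experiment

RetainP_1:
  kind: model
  dataset: experiment
  family: binomial-logit
  response: [n_palmelloid_cells, n_single]
  fixed_terms:
    - {factor: predation}
    - {factor: nitrate}
    - {factor: turbulence}
    - {factor: ecm_present}
    - {covariate: prop_palmelloid_t0, transform: logit, denominator: n_classified}
  random: random_experiment
  filters:
    - {drop_zero_trials: [n_palmelloid_cells, n_single]}

Mu_1:
  kind: model
  dataset: experiment
  family: binomial-logit
  response: [ecm_single, n_ecm_no]
  fixed_terms:
    - {factor: predation}
    - {factor: nitrate}
    - {factor: turbulence}
  random: random_experiment
  filters:
    - {drop_strains_all_zero: ecm_single}

Lake_ECM:
  kind: model
  dataset: lake
  family: binomial-logit
  response: [n_species_ecm, n_species_no_ecm]
  fixed_terms:
    - {covariate: log_ammonium, transform: z}
    - {covariate: log_nitratenitrite, transform: z}
  random: random_lake
  filters:
    - {keep_where_zero: n_species_multicellular}

Lake_MC:
  kind: model
  dataset: lake
  family: binomial-logit
  response: [n_species_multicellular, n_species_unicellular]
  fixed_terms:
    - {factor: ecm}
    - {covariate: log_ammonium, transform: z}
    - {covariate: log_nitratenitrite, transform: z}
    - {interaction: [{factor: ecm}, {covariate: log_ammonium, transform: z}]}
  random: random_lake

V1:
  kind: model
  dataset: lake
  family: binomial-logit
  response: [n_species_ecm, n_species_no_ecm]
  fixed_terms:
    - {covariate: ratio_np, transform: z}
  random: random_lake
  filters:
    - {keep_where_zero: n_species_multicellular}

V2:
  kind: model
  dataset: lake
  family: binomial-logit
  response: [n_species_multicellular, n_species_unicellular]
  fixed_terms:
    - {factor: ecm}
    - {covariate: ratio_np, transform: z}
    - {interaction: [{factor: ecm}, {covariate: ratio_np, transform: z}]}
  random: random_lake

Path_1.1:
  kind: path
  dataset: experiment
  variables:
    ecm: ecm01
    palmelloid: logit_palmelloid
    group: logit_group
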