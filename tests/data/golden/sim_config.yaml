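bottleneck_cells: null
control_doublings: 8.0
essential_fitness: -0.3
essentiality_prior_sd: 0.05
frac_essential: 0.2
guide_efficiency_alpha: 5.0
guide_efficiency_beta: 1.0
guides_per_gene: 10
interaction_effect: 0.4
n_control_guides: 20
n_enhancers: 3
n_genes: 40
n_passages: 4
n_screens: 2
n_suppressors: 2
reads_per_sample: null
seed: 1234
treated_doublings: 5.0
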