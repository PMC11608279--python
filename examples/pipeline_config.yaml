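# Full-pipeline configuration (see hicost.pipeline.PipelineConfig).
# Run with:  hicost run-all --config examples/pipeline_config.yaml
out_dir: pipeline_demo
simulate_n_patients: 20000     # or set claims_dir to load real tables
year: 2019
high_cost_fraction: 0.10
adrg_min_prevalence: 0.01
comorbidity_min_prevalence: 0.001
pca_variance_target: 0.80
tsne_perplexity: 30
tsne_theta: 0.5
optics_min_samples: [10, 20, 40, 80]
optics_xi: [0.01, 0.02, 0.05]
min_clusters: 5
min_cluster_share: 0.01
run_comparators: false
# merge_map_path: merge_map.csv   # CSV cluster_id,subgroup from expert review
master_seed: 42
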