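# Five-condition demo pipeline: simulate -> features -> motility ->
# summarize -> classify -> pls. See morphoinvasion.pipeline.PipelineConfig
# for all keys.
outdir: results/pipeline_demo
seed: 0
study: default          # or "recovery" for the 8-condition coupled study
n_cells: 60
speed_threshold: 0.5    # µm/min; mean speed strictly above -> "high"
invasion_threshold: 10.0  # fold change strictly above -> "high"
classifier_rates: [1.0]
classifier_estimators: [50]
pls_components: auto
pls_n_perm: 200
pls_responses: [speed, persistence, invasion]
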