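# Full-pipeline run on a synthetic cohort calibrated to the study marginals.
# Swap the [synthetic] block for `paths.data = "your_cohort.csv"` to analyse
# real data (raw questionnaire columns or pre-derived analysis columns).

[paths]
dag = "examples/study_reconstructed.dag"
out_dir = "results/example_run"

[analysis]
mediator_scale = "raw"
mc_draws = 100
bootstrap_b = 1000
seed = 7
ci_level = 0.95

[synthetic]
preset = "study"
n = 169
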