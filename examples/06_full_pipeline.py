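"""Run the complete analysis pipeline and print the report summary.

Equivalent to `phonrestore run --out out/ --seed 5` with the configuration
below; every stage consumes seeds spawned from the single configured seed,
so the JSON report is byte-identical across runs.
"""

from phonrestore.config import (
    ClassifySection, PipelineConfig, ReconstructSection, RestorationSection,
    SynthSection)
from phonrestore.pipeline import render_summary, run_pipeline

cfg = PipelineConfig(
    seed=5,
    synth=SynthSection(n_electrodes=36, grid_shape=(6, 6),
                       n_trials_per_condition=16, n_word_pairs=2,
                       n_contrast_electrodes=12, n_bias_electrodes=6,
                       restoration_gain=0.7, bias_amplitude=0.8),
    restoration=RestorationSection(n_boot=200),
    reconstruct=ReconstructSection(corpus_duration_s=90.0, ridge_penalty=100.0),
    classify=ClassifySection(time_range=(-0.1, 0.9)),
)
report = run_pipeline(cfg)
print(render_summary(report))
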