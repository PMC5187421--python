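"""Schema-validated pipeline configuration.

One YAML document holds every module's tunables; unknown keys are rejected
(pydantic ``extra='forbid'``) and every random operation consumes an explicit
seed derived from ``seed`` via ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SynthSection(_Strict):
    n_electrodes: int = 64
    grid_shape: tuple[int, int] = (8, 8)
    grid_pitch_mm: float = 4.0
    n_trials_per_condition: int = Field(default=12, ge=2)
    sample_rate: float = 1000.0
    frame_rate: float = 100.0
    percept_bias_strength: float = 0.85
    n_word_pairs: int = 2
    n_freq_bins: int = 32
    cp_window: tuple[float, float] = (0.30, 0.50)
    word_duration: float = 0.8
    contrast_band: tuple[float, float] = (3000.0, 8000.0)
    restoration_gain: float = 0.6
    restoration_latency: float = 0.15
    bias_amplitude: float = 0.5
    n_contrast_electrodes: int = 12
    n_bias_electrodes: int = 8
    noise_sd: float = 0.3
    env_noise_sd: float = 0.3


class PreprocessSection(_Strict):
    band: tuple[float, float] = (70.0, 150.0)
    frame_rate: float = 100.0
    variance_z_cutoff: float = 5.0
    window: tuple[float, float] = (-0.5, 1.1)
    baseline: tuple[float, float] = (-0.5, 0.0)
    baseline_mode: str = "per_trial"


class RestorationSection(_Strict):
    zscore_threshold: float = 1.5
    n_boot: int = 1000
    ci_level: float = 0.99
    smooth_window_frames: int = 5
    analysis_window: tuple[float, float] = (-0.3, 0.6)
    alpha: float = 0.05


class ReconstructSection(_Strict):
    lags: tuple[float, float] = (-0.3, 0.0)
    ridge_penalty: float | str = "cv"
    corpus_duration_s: float = 120.0
    percentile: float = 90.0


class DynamicsSection(_Strict):
    n_pc: int = 10


class ClassifySection(_Strict):
    window_len: float = 0.110
    time_range: tuple[float, float] | None = None
    pre_window: tuple[float, float] = (-0.3, 0.0)
    post_window: tuple[float, float] = (0.0, 0.3)


class PipelineConfig(_Strict):
    """All module defaults in one schema-validated document."""

    seed: int = 0
    synth: SynthSection = Field(default_factory=SynthSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    restoration: RestorationSection = Field(default_factory=RestorationSection)
    reconstruct: ReconstructSection = Field(default_factory=ReconstructSection)
    dynamics: DynamicsSection = Field(default_factory=DynamicsSection)
    classify: ClassifySection = Field(default_factory=ClassifySection)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            doc = yaml.safe_load(f) or {}
        return cls.model_validate(doc)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.model_dump(), f, sort_keys=True)

    def spawn_seeds(self, n: int) -> list[int]:
        """Independent child seeds (below 2**31) derived from ``seed``."""
        ss = np.random.SeedSequence(self.seed)
        return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
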