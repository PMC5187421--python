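"""Shared fixtures: small synthetic datasets built once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phonrestore.config import PipelineConfig, SynthSection
from phonrestore.pipeline import simulate_dataset
from phonrestore.preprocess import (
    Epochs,
    common_average_reference,
    epoch_and_zscore,
    extract_high_gamma,
    reject_channels,
)


def small_config(seed: int = 0, **synth_kwargs) -> PipelineConfig:
    defaults = dict(
        n_electrodes=36,
        grid_shape=(6, 6),
        n_trials_per_condition=12,
        n_word_pairs=1,
        n_contrast_electrodes=8,
        n_bias_electrodes=4,
    )
    defaults.update(synth_kwargs)
    return PipelineConfig(seed=seed, synth=SynthSection(**defaults))


def preprocess_chain(rec, trials, electrodes, window=(-0.5, 1.1)):
    rec = reject_channels(rec, 5.0)
    rec = common_average_reference(rec, electrodes)
    rec = extract_high_gamma(rec)
    return epoch_and_zscore(rec, trials, window=window)


def synthetic_epochs(
    n_e: int = 6,
    n_f: int = 160,
    n_per_cell: int = 10,
    rng: np.random.Generator | None = None,
    frame_rate: float = 100.0,
    t0: float = -0.5,
) -> tuple[Epochs, pd.DataFrame]:
    """Directly constructed z-scored epochs with a standard trial table.

    Four cells (orig1, orig2, noise-p1, noise-p2), pure N(0,1) data; tests
    plant effects on top of the returned arrays.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    conds = (["orig1"] * n_per_cell + ["orig2"] * n_per_cell + ["noise"] * 2 * n_per_cell)
    percs = [1] * n_per_cell + [2] * n_per_cell + [1] * n_per_cell + [2] * n_per_cell
    n_t = len(conds)
    data = rng.standard_normal((n_e, n_f, n_t))
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(n_t),
            "word_pair_id": "wp0",
            "condition": conds,
            "reported_percept": percs,
            "bias_state_truth": 0,
            "word_onset_s": 0.0,
            "cp_onset_s": 0.3,
            "cp_offset_s": 0.5,
            "word_offset_s": 0.7,
        }
    )
    ep = Epochs(
        data=data,
        frame_rate=frame_rate,
        t0=t0,
        channel_ids=[f"e{i:03d}" for i in range(n_e)],
    )
    return ep, trials


@pytest.fixture(scope="session")
def sim_dataset():
    """One small simulated dataset with planted restoration and bias."""
    cfg = small_config(seed=11, n_trials_per_condition=16, restoration_gain=0.7,
                       bias_amplitude=0.8)
    rec, trials, electrodes, triplets, fm, aux_seed = simulate_dataset(cfg)
    return dict(cfg=cfg, rec=rec, trials=trials, electrodes=electrodes,
                triplets=triplets, fm=fm, aux_seed=aux_seed)


@pytest.fixture(scope="session")
def sim_epochs(sim_dataset):
    """The same dataset taken through the preprocessing chain."""
    ep = preprocess_chain(sim_dataset["rec"], sim_dataset["trials"],
                          sim_dataset["electrodes"])
    return ep
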