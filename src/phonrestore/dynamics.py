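"""Neural state-space analysis.

Trial-resolved population activity is reshaped into an
(time points x trials) by electrodes matrix and decomposed by PCA; the
component scores, reshaped back to time x trials, trace low-dimensional
trajectories through a neural state space, and the electrode weights of each
component localize its cortical contributors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from phonrestore.preprocess import Epochs


@dataclass
class StateSpace:
    """PCA of population activity over (time x trials) observations."""

    components: np.ndarray  # (electrodes, n_pc), orthonormal columns
    scores: np.ndarray  # (frames, trials, n_pc)
    explained_variance_ratio: np.ndarray
    channel_ids: list[str]
    frame_rate: float
    t0: float
    mean_: np.ndarray  # per-electrode centering offsets
    condition_means: dict[str, np.ndarray]  # label -> (frames, n_pc)


def fit_state_space(ep: Epochs, trials: pd.DataFrame, n_pc: int = 10) -> StateSpace:
    """PCA on the (frames*trials) x electrodes matrix after mean-centering.

    Inputs are baseline z-scored already, so only column means are removed
    (no per-electrode variance scaling).  Scores are reshaped back to
    frames x trials; per-condition (orig1/orig2) and per-noise-percept mean
    trajectories are included.  Component signs are stabilized so each
    component's maximum-|weight| electrode has a positive weight.
    """
    n_e, n_f, n_t = ep.data.shape
    if n_pc > n_e:
        raise ValueError(f"n_pc={n_pc} exceeds the number of electrodes ({n_e})")
    x = ep.data.transpose(1, 2, 0).reshape(n_f * n_t, n_e)  # rows ordered (frame, trial)
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    if n_pc > rank:
        raise ValueError(f"n_pc={n_pc} exceeds the data rank ({rank})")
    pca = PCA(n_components=n_pc, svd_solver="full")
    scores = pca.fit_transform(x)

    comps = pca.components_.T.copy()  # (electrodes, n_pc)
    for k in range(n_pc):
        if comps[np.argmax(np.abs(comps[:, k])), k] < 0:
            comps[:, k] *= -1
            scores[:, k] *= -1
    scores = scores.reshape(n_f, n_t, n_pc)

    cond_means: dict[str, np.ndarray] = {}
    cond = trials["condition"].to_numpy()
    perc = trials["reported_percept"].to_numpy()
    for label, mask in (
        ("orig1", cond == "orig1"),
        ("orig2", cond == "orig2"),
        ("noise_p1", (cond == "noise") & (perc == 1)),
        ("noise_p2", (cond == "noise") & (perc == 2)),
    ):
        if mask.any():
            cond_means[label] = scores[:, mask, :].mean(axis=1)

    return StateSpace(
        components=comps,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        channel_ids=list(ep.channel_ids),
        frame_rate=ep.frame_rate,
        t0=ep.t0,
        mean_=pca.mean_,
        condition_means=cond_means,
    )


def electrode_weight_map(
    ss: StateSpace, electrode_table: pd.DataFrame, pc_index: int
) -> pd.DataFrame:
    """Per-electrode weight table for one component, for spatial plotting."""
    if not 0 <= pc_index < ss.components.shape[1]:
        raise IndexError(f"pc_index {pc_index} out of range")
    meta = electrode_table.set_index("id")
    rows = []
    for cid, w in zip(ss.channel_ids, ss.components[:, pc_index]):
        m = meta.loc[cid]
        rows.append(
            {
                "id": cid,
                "x_mm": m["x_mm"],
                "y_mm": m["y_mm"],
                "region": m["region"],
                "hemisphere": m["hemisphere"],
                "weight": float(w),
            }
        )
    return pd.DataFrame(rows)
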