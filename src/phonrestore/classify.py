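"""Single-trial, time-resolved percept classification.

Linear support-vector machines (fixed unit regularization, identical
parameters everywhere) are trained at each frame on features formed by
concatenating electrode responses over a sliding symmetric 110 ms window,
with leave-one-out cross-validation.  Original-trial classifiers predict the
stimulus word, noise-trial classifiers the reported percept (chance = 50%).
Squared weights, averaged over a window's lag copies and across folds,
localize each electrode's contribution; pre- vs post-critical-phoneme
windows are compared with Welch t tests (Bonferroni corrected) and a
three-way hemisphere x location x condition ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.svm import SVC

from phonrestore.preprocess import Epochs
from phonrestore.times import time_to_frame

#: default mapping of electrode region to Sylvian-fissure location
LOCATION_MAP = {
    "IFG": "supra",
    "precentral": "supra",
    "postcentral": "supra",
    "STG": "sub",
    "MTG": "sub",
    "other": "sub",
}

CHANCE = 0.5


@dataclass
class ClassifierTimecourse:
    """Per-frame LOO accuracy and per-electrode mean squared weights."""

    condition_set: str
    accuracy: np.ndarray  # (frames,), NaN outside the evaluated range
    weights: np.ndarray  # (electrodes, frames), squared-coefficient means
    times: np.ndarray
    frames: np.ndarray  # evaluated frame indices
    n_trials: int
    window_len: float
    channel_ids: list[str]
    chance: float = CHANCE


@dataclass
class WeightStats:
    """Window-averaged weight statistics with ANOVA and post-hoc contrasts."""

    table: pd.DataFrame  # electrode x condition x window long table
    anova: dict[str, pd.DataFrame]  # window -> type-II ANOVA table
    posthoc: pd.DataFrame
    windows: dict[str, tuple[float, float]] = field(default_factory=dict)


def _trial_set(trials: pd.DataFrame, condition_set: str) -> tuple[np.ndarray, np.ndarray]:
    if condition_set == "original":
        mask = trials["condition"].isin(["orig1", "orig2"]).to_numpy()
        labels = np.where(trials.loc[mask, "condition"].to_numpy() == "orig1", 1, 2)
    elif condition_set == "noise":
        mask = (trials["condition"] == "noise").to_numpy()
        labels = trials.loc[mask, "reported_percept"].to_numpy()
    else:
        raise ValueError(f"unknown condition_set {condition_set!r}")
    return mask, labels


def _window_bounds(center: int, half: int, n_frames: int) -> tuple[int, int]:
    return max(0, center - half), min(n_frames, center + half + 1)


def _fit_svm(x: np.ndarray, y: np.ndarray) -> SVC:
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(x, y)
    return clf


def classify_timecourse(
    ep: Epochs,
    trials: pd.DataFrame,
    condition_set: str,
    window_len: float = 0.110,
    seed: int = 0,
    time_range: tuple[float, float] | None = None,
) -> ClassifierTimecourse:
    """Leave-one-out linear-SVM accuracy at every frame.

    Features at frame j concatenate all electrodes over the symmetric
    ``window_len`` window centred on j (truncated at epoch edges).  Accuracy
    is the fraction of held-out trials whose predicted label matches the
    trial's label; weights are per-electrode means of squared coefficients
    over the window's frame copies, averaged across folds.  ``time_range``
    (seconds relative to word onset) restricts the evaluated frames.
    """
    del seed  # the LOO/SVM path is deterministic; kept for interface stability
    mask, labels = _trial_set(trials, condition_set)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError(
            f"need >=2 trials in each of two classes, got {dict(zip(classes, counts))}"
        )
    data = ep.data[:, :, mask]
    n_e, n_frames, n_t = data.shape
    half = int(round(window_len * ep.frame_rate / 2))

    if time_range is None:
        frames = np.arange(n_frames)
    else:
        lo = max(0, time_to_frame(time_range[0], ep.frame_rate, ep.t0))
        hi = min(n_frames, time_to_frame(time_range[1], ep.frame_rate, ep.t0) + 1)
        frames = np.arange(lo, hi)

    accuracy = np.full(n_frames, np.nan)
    weights = np.full((n_e, n_frames), np.nan)
    for j in frames:
        lo_f, hi_f = _window_bounds(j, half, n_frames)
        feats = data[:, lo_f:hi_f, :].reshape(n_e * (hi_f - lo_f), n_t).T
        correct = 0
        wsum = np.zeros(n_e)
        degenerate = False
        for i in range(n_t):
            keep = np.arange(n_t) != i
            if np.ptp(feats[keep], axis=0).max() == 0:
                degenerate = True
            clf = _fit_svm(feats[keep], labels[keep])
            if clf.predict(feats[i : i + 1])[0] == labels[i]:
                correct += 1
            coef = clf.coef_.reshape(n_e, hi_f - lo_f)
            wsum += (coef**2).mean(axis=1)
        if degenerate:
            warnings.warn(f"identical features across classes at frame {j}; margin collapsed")
        accuracy[j] = correct / n_t
        weights[:, j] = wsum / n_t
    return ClassifierTimecourse(
        condition_set=condition_set,
        accuracy=accuracy,
        weights=weights,
        times=ep.times,
        frames=frames,
        n_trials=n_t,
        window_len=window_len,
        channel_ids=list(ep.channel_ids),
    )


def temporal_generalization(
    ep: Epochs,
    trials: pd.DataFrame,
    condition_set: str,
    train_window_center: int,
    train_window_len: float = 0.110,
) -> np.ndarray:
    """Train at one window per LOO fold, test the held-out trial everywhere.

    Returns a per-frame accuracy trace.  Only frames where the full window
    fits inside the epoch are evaluated (a classifier trained on full-window
    features cannot consume a truncated feature vector); other frames are
    NaN.  At the training frame this equals the per-frame accuracy of
    :func:`classify_timecourse` (same folds, same features).
    """
    mask, labels = _trial_set(trials, condition_set)
    data = ep.data[:, :, mask]
    n_e, n_frames, n_t = data.shape
    half = int(round(train_window_len * ep.frame_rate / 2))
    lo_t, hi_t = train_window_center - half, train_window_center + half + 1
    if lo_t < 0 or hi_t > n_frames:
        raise ValueError("train window does not fit inside the epoch")
    wlen = hi_t - lo_t

    def feats_at(j):
        return data[:, j - half : j + half + 1, :].reshape(n_e * wlen, n_t).T

    train_feats = feats_at(train_window_center)
    valid = np.arange(half, n_frames - half)
    correct = np.zeros(n_frames)
    for i in range(n_t):
        keep = np.arange(n_t) != i
        clf = _fit_svm(train_feats[keep], labels[keep])
        for j in valid:
            pred = clf.predict(feats_at(j)[i : i + 1])[0]
            if pred == labels[i]:
                correct[j] += 1
    acc = np.full(n_frames, np.nan)
    acc[valid] = correct[valid] / n_t
    return acc


def weight_localization(
    tc_orig: ClassifierTimecourse,
    tc_noise: ClassifierTimecourse,
    electrode_table: pd.DataFrame,
    cp_onset: float,
    pre: tuple[float, float] = (-0.3, 0.0),
    post: tuple[float, float] = (0.0, 0.3),
    location_map: dict[str, str] | None = None,
    contrasts: list[tuple[str, str]] | None = None,
) -> WeightStats:
    """Window-average squared weights and run localization statistics.

    ``pre``/``post`` are seconds relative to critical-phoneme onset.  A
    three-way fixed-effects ANOVA (hemisphere x location x condition,
    type-II sums of squares) is run per window on electrode mean weights;
    post-hoc Welch t tests compare noise vs original weights within frontal
    (supra-Sylvian) and temporal (sub-Sylvian) electrode groups per window,
    Bonferroni-adjusted over the number of contrasts.
    """
    if location_map is None:
        location_map = LOCATION_MAP
    meta = electrode_table.set_index("id")
    windows = {"pre": pre, "post": post}
    rows = []
    for cond, tc in (("original", tc_orig), ("noise", tc_noise)):
        for wname, (w0, w1) in windows.items():
            sel = (tc.times >= cp_onset + w0) & (tc.times < cp_onset + w1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                wmean = np.nanmean(tc.weights[:, sel], axis=1)
            for cid, w in zip(tc.channel_ids, wmean):
                m = meta.loc[cid]
                rows.append(
                    {
                        "electrode": cid,
                        "hemisphere": m["hemisphere"],
                        "location": location_map.get(m["region"], "sub"),
                        "condition": cond,
                        "window": wname,
                        "weight": float(w),
                    }
                )
    table = pd.DataFrame(rows).dropna(subset=["weight"])

    anova: dict[str, pd.DataFrame] = {}
    for wname in windows:
        sub = table[table["window"] == wname]
        factors = []
        for f in ("hemisphere", "location", "condition"):
            if sub[f].nunique() > 1:
                factors.append(f"C({f})")
            else:
                warnings.warn(f"factor {f!r} has a single level in window {wname!r}; dropped")
        if not factors:
            continue
        formula = "weight ~ " + "*".join(factors)
        fit = smf.ols(formula, data=sub).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        # no variance at all -> define every F as exactly 0 (0/0 otherwise)
        scale = float(np.mean(np.square(sub["weight"])))
        if float(sub["weight"].var()) <= 1e-12 * max(scale, 1e-300):
            tab["F"] = np.where(tab["df"].notna() & (tab.index != "Residual"), 0.0, np.nan)
            tab["PR(>F)"] = np.where(np.isfinite(tab["F"]), 1.0, np.nan)
        anova[wname] = tab

    if contrasts is None:
        contrasts = [("pre", "supra"), ("pre", "sub"), ("post", "supra"), ("post", "sub")]
    ph_rows = []
    n_contrasts = len(contrasts)
    for wname, loc in contrasts:
        sub = table[(table["window"] == wname) & (table["location"] == loc)]
        a = sub.loc[sub["condition"] == "noise", "weight"].to_numpy()
        b = sub.loc[sub["condition"] == "original", "weight"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        if a.var() == 0 and b.var() == 0:
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
        ph_rows.append(
            {
                "window": wname,
                "location": loc,
                "contrast": "noise - original",
                "t": float(t),
                "p_raw": float(p),
                "p_bonf": float(min(1.0, p * n_contrasts)),
                "mean_noise": float(a.mean()),
                "mean_original": float(b.mean()),
            }
        )
    return WeightStats(
        table=table,
        anova=anova,
        posthoc=pd.DataFrame(ph_rows),
        windows=windows,
    )
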