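"""Restoration-index analysis.

Quantifies neural phoneme restoration per electrode and time point: electrode
selection by original-vs-original z-score contrast, bootstrap 99% CI criteria
on evoked traces, the restoration index

    RI(i, j) = (D2 - D1) / D0

where D1/D2 are Euclidean distances between the noise-trial trace and each
original-trial trace over a short window centred on frame j, and D0 the
distance between the two originals, and group-level aggregation of |dRI|
across electrodes/word pairs with per-frame t tests and Benjamini-Hochberg
FDR correction over the analysis frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from phonrestore.preprocess import Epochs
from phonrestore.times import frame_slice, time_to_frame


@dataclass
class ElectrodeSelection:
    """Electrodes that discriminate the two original words of a pair."""

    word_pair_id: str
    selected: list[str]
    zscore_threshold: float
    window: tuple[float, float]
    max_abs_diff: pd.Series  # per-electrode max |orig1 - orig2| z over the window


@dataclass
class CiCriteria:
    """Bootstrap CI overlap criteria per selected electrode and frame.

    ``orig_differ``: Orig1 != Orig2; ``noise1_matches_orig1``:
    (Orig1 = Noise1) & (Orig1 != Noise2); ``noise2_matches_orig2``:
    (Orig2 = Noise2) & (Orig2 != Noise1).  "=" means overlapping CIs, "!="
    disjoint CIs.  When a noise-percept cell is empty (non-bistable pair),
    the disjointness clause against it is dropped.
    """

    channel_ids: list[str]
    orig_differ: np.ndarray
    noise1_matches_orig1: np.ndarray | None
    noise2_matches_orig2: np.ndarray | None
    n_boot: int
    ci_level: float


@dataclass
class RiResult:
    """Per-electrode, per-frame restoration index traces for one word pair.

    ``ri`` is (electrodes x frames x 2), one slab per percept (NaN where the
    percept has no noise trials or where D0 = 0); ``d1``/``d2`` likewise per
    percept; ``abs_dri`` is |RI_percept1 - RI_percept2|.
    """

    word_pair_id: str
    channel_ids: list[str]
    ri: np.ndarray
    d0: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    abs_dri: np.ndarray
    frame_rate: float
    t0: float
    cp_onset: float


@dataclass
class GroupRi:
    """Group-level |dRI| statistics over the analysis window."""

    times: np.ndarray  # seconds relative to cp onset
    mean: np.ndarray
    tstat: np.ndarray
    p: np.ndarray
    q: np.ndarray
    sig: np.ndarray
    n_electrodes: int

    def earliest_sig_time(self) -> float | None:
        idx = np.flatnonzero(self.sig)
        return None if idx.size == 0 else float(self.times[idx[0]])


def _cond_mask(trials: pd.DataFrame, word_pair_id: str, cond: str,
               percept: int | None = None) -> np.ndarray:
    m = (trials["word_pair_id"] == word_pair_id) & (trials["condition"] == cond)
    if percept is not None:
        m &= trials["reported_percept"] == percept
    return m.to_numpy()


def select_electrodes(
    ep: Epochs,
    trials: pd.DataFrame,
    word_pair_id: str,
    zscore_threshold: float = 1.5,
    window: tuple[float, float] | None = None,
) -> ElectrodeSelection:
    """Select electrodes whose orig1-vs-orig2 trial-mean difference exceeds
    ``zscore_threshold`` (baseline-z units) at >= 1 frame in ``window``.

    The default window runs from critical-phoneme onset to word offset.
    """
    m1 = _cond_mask(trials, word_pair_id, "orig1")
    m2 = _cond_mask(trials, word_pair_id, "orig2")
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError(f"word pair {word_pair_id!r} needs >=2 trials per original condition")
    row = trials[trials["word_pair_id"] == word_pair_id].iloc[0]
    if window is None:
        window = (float(row["cp_onset_s"]), float(row.get("word_offset_s", ep.times[-1])))
    sl = frame_slice(window, ep.frame_rate, ep.t0)
    diff = np.abs(
        ep.data[:, sl, m1].mean(axis=2) - ep.data[:, sl, m2].mean(axis=2)
    )
    max_abs = pd.Series(diff.max(axis=1), index=ep.channel_ids)
    selected = [c for c in ep.channel_ids if max_abs[c] > zscore_threshold]
    if not selected:
        warnings.warn(f"no electrode passed |z| > {zscore_threshold} for {word_pair_id!r}")
    return ElectrodeSelection(
        word_pair_id=word_pair_id,
        selected=selected,
        zscore_threshold=zscore_threshold,
        window=window,
        max_abs_diff=max_abs,
    )


def _boot_ci(data: np.ndarray, idx: np.ndarray, level: float) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap CI of the trial mean.

    ``data`` is (electrodes, frames, trials); ``idx`` is (n_boot, n_trials)
    resampled trial indices.  Returns (lo, hi), each (electrodes, frames).
    """
    boot_means = data[:, :, idx].mean(axis=3)  # (E, F, n_boot)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot_means, [alpha, 1.0 - alpha], axis=2)
    return lo, hi


def bootstrap_ci_criteria(
    ep: Epochs,
    trials: pd.DataFrame,
    selection: ElectrodeSelection,
    n_boot: int = 1000,
    level: float = 0.99,
    seed: int = 0,
) -> CiCriteria:
    """Evaluate the three CI overlap criteria per electrode and frame.

    Trial means are resampled with replacement within each condition cell
    (orig1, orig2, noise-perceived-1, noise-perceived-2); "!=" means the two
    percentile CIs are disjoint, "=" that they overlap.  Seeded and
    reproducible.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; CI endpoints will be noisy")
    wp = selection.word_pair_id
    chan_idx = [ep.channel_ids.index(c) for c in selection.selected]
    data = ep.data[chan_idx]
    rng = np.random.default_rng(seed)

    cells = {
        "orig1": _cond_mask(trials, wp, "orig1"),
        "orig2": _cond_mask(trials, wp, "orig2"),
        "noise1": _cond_mask(trials, wp, "noise", percept=1),
        "noise2": _cond_mask(trials, wp, "noise", percept=2),
    }
    for name in ("orig1", "orig2"):
        if cells[name].sum() < 2:
            raise ValueError(f"cell {name!r} of word pair {wp!r} has fewer than 2 trials")

    cis: dict[str, tuple[np.ndarray, np.ndarray] | None] = {}
    for name, mask in cells.items():
        n = int(mask.sum())
        if n == 0:
            cis[name] = None
            continue
        idx = rng.integers(0, n, size=(n_boot, n))
        cis[name] = _boot_ci(data[:, :, mask], idx, level)

    def disjoint(a, b):
        (lo_a, hi_a), (lo_b, hi_b) = a, b
        return (lo_a > hi_b) | (lo_b > hi_a)

    def overlap(a, b):
        return ~disjoint(a, b)

    orig_differ = disjoint(cis["orig1"], cis["orig2"])

    def match_criterion(noise_name: str, same: str, other: str):
        if cis[noise_name] is None:
            return None
        crit = overlap(cis[noise_name], cis[same])
        other_noise = "noise2" if noise_name == "noise1" else "noise1"
        if cis[other_noise] is not None:
            crit &= disjoint(cis[same], cis[other_noise])
        return crit

    return CiCriteria(
        channel_ids=list(selection.selected),
        orig_differ=orig_differ,
        noise1_matches_orig1=match_criterion("noise1", "orig1", "orig2"),
        noise2_matches_orig2=match_criterion("noise2", "orig2", "orig1"),
        n_boot=n_boot,
        ci_level=level,
    )


def _windowed_distance(a: np.ndarray, b: np.ndarray, half: int) -> np.ndarray:
    """Euclidean distance between trial-mean traces over a centred window.

    ``a``/``b`` are (electrodes, frames); the window around frame j is
    truncated at the array bounds.  Returns (electrodes, frames).
    """
    sq = (a - b) ** 2
    n_frames = sq.shape[1]
    acc = np.zeros_like(sq)
    for off in range(-half, half + 1):
        lo = max(0, -off)
        hi = min(n_frames, n_frames - off)
        acc[:, lo:hi] += sq[:, lo + off : hi + off]
    return np.sqrt(acc)


def restoration_index(
    ep: Epochs,
    trials: pd.DataFrame,
    selection: ElectrodeSelection,
    smooth_window_frames: int = 5,
) -> RiResult:
    """Compute RI = (D2 - D1) / D0 per selected electrode, frame and percept.

    D1 is the distance of the noise-trial mean trace (for the given percept)
    from the orig1 trace, D2 from the orig2 trace, and D0 the distance
    between the originals, each over a ``smooth_window_frames`` window
    centred on the frame.  Frames with D0 = 0 are emitted as NaN, never as
    +/-inf.  RI is +1 when the noise trace equals orig1 exactly and -1 when
    it equals orig2.
    """
    if not selection.selected:
        raise ValueError("electrode selection is empty")
    if smooth_window_frames < 1 or smooth_window_frames % 2 == 0:
        raise ValueError("smooth_window_frames must be a positive odd number")
    half = smooth_window_frames // 2
    wp = selection.word_pair_id
    chan_idx = [ep.channel_ids.index(c) for c in selection.selected]
    data = ep.data[chan_idx]

    mean1 = data[:, :, _cond_mask(trials, wp, "orig1")].mean(axis=2)
    mean2 = data[:, :, _cond_mask(trials, wp, "orig2")].mean(axis=2)
    d0 = _windowed_distance(mean1, mean2, half)

    n_e, n_f = mean1.shape
    ri = np.full((n_e, n_f, 2), np.nan)
    d1 = np.full((n_e, n_f, 2), np.nan)
    d2 = np.full((n_e, n_f, 2), np.nan)
    for p in (1, 2):
        mask = _cond_mask(trials, wp, "noise", percept=p)
        if mask.sum() == 0:
            continue
        noise_mean = data[:, :, mask].mean(axis=2)
        d1[:, :, p - 1] = _windowed_distance(noise_mean, mean1, half)
        d2[:, :, p - 1] = _windowed_distance(noise_mean, mean2, half)
        with np.errstate(invalid="ignore", divide="ignore"):
            val = (d2[:, :, p - 1] - d1[:, :, p - 1]) / d0
        val[d0 == 0] = np.nan
        ri[:, :, p - 1] = val

    abs_dri = np.abs(ri[:, :, 0] - ri[:, :, 1])
    row = trials[trials["word_pair_id"] == wp].iloc[0]
    return RiResult(
        word_pair_id=wp,
        channel_ids=list(selection.selected),
        ri=ri,
        d0=d0,
        d1=d1,
        d2=d2,
        abs_dri=abs_dri,
        frame_rate=ep.frame_rate,
        t0=ep.t0,
        cp_onset=float(row["cp_onset_s"]),
    )


def aggregate_ri(
    results: list[RiResult],
    bistable: list[bool],
    perceived: list[int] | None = None,
    analysis_window: tuple[float, float] = (-0.3, 0.6),
    alpha: float = 0.05,
) -> GroupRi:
    """Combine RI across word pairs and test each frame against baseline.

    Bistable pairs contribute |RI_percept1 - RI_percept2| per electrode and
    frame; non-bistable pairs contribute the RI of the single observed
    percept, signed positive toward the perceived word.  Each electrode's
    pre-critical-phoneme mean is subtracted (the statistic is a
    baseline-referenced increase), then a per-frame one-sided t test across
    electrodes is FDR-corrected (Benjamini-Hochberg) over the analysis
    frames: ``analysis_window`` is relative to critical-phoneme onset and
    spans 91 frames at the default 100 Hz rate.
    """
    if not results:
        raise ValueError("no word-pair results to aggregate")
    if perceived is None:
        perceived = [1] * len(results)

    rows = []
    times = None
    for res, bi, perc in zip(results, bistable, perceived):
        fr = res.frame_rate
        j0 = time_to_frame(res.cp_onset + analysis_window[0], fr, res.t0)
        n_frames = int(round((analysis_window[1] - analysis_window[0]) * fr)) + 1
        if j0 < 0 or j0 + n_frames > res.abs_dri.shape[1]:
            raise ValueError("analysis window does not fit inside the RI traces")
        if times is None:
            times = analysis_window[0] + np.arange(n_frames) / fr
        if bi:
            vals = res.abs_dri[:, j0 : j0 + n_frames]
        else:
            signed = res.ri[:, :, perc - 1] * (1 if perc == 1 else -1)
            vals = signed[:, j0 : j0 + n_frames]
        rows.append(vals)

    x = np.concatenate(rows, axis=0)
    if x.shape[0] == 0:
        raise ValueError("zero electrodes across all word pairs")
    baseline_cols = times < 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        x = x - np.nanmean(x[:, baseline_cols], axis=1, keepdims=True)
        t, p = scipy.stats.ttest_1samp(
            x, 0.0, axis=0, nan_policy="omit", alternative="greater"
        )
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    ok = np.isfinite(p)
    q = np.full_like(p, np.nan)
    sig = np.zeros_like(p, dtype=bool)
    if ok.any():
        rej, q_ok, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        q[ok] = q_ok
        sig[ok] = rej
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(x, axis=0)
    return GroupRi(
        times=times,
        mean=mean,
        tstat=t,
        p=p,
        q=q,
        sig=sig,
        n_electrodes=x.shape[0],
    )
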