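"""Raw voltage -> baseline-normalized high-gamma analytic-amplitude epochs.

The stages mirror standard ECoG practice: channel rejection, common average
referencing across electrode-grid rows, band-pass filtering to the high-gamma
range (70-150 Hz) followed by Hilbert-envelope extraction and decimation, and
finally epoching with per-trial z-scoring against a 500 ms pre-stimulus
baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.signal

from phonrestore.times import frame_slice

STAGES = ("raw", "referenced", "highgamma", "zscored")


class PipelineError(RuntimeError):
    """Raised when a preprocessing stage cannot produce a valid output."""


@dataclass
class Recording:
    """Multichannel neural time series at one processing stage.

    ``data`` is ``(electrodes, samples)`` for continuous recordings or
    ``(electrodes, samples, trials)`` for epoched ones.  ``t0`` is the time of
    sample 0 in seconds relative to word onset (meaningful for epoched data).
    """

    data: np.ndarray
    sample_rate: float
    stage: str
    channel_ids: list[str]
    bad_channels: set[str] = field(default_factory=set)
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if len(self.channel_ids) != len(set(self.channel_ids)):
            raise ValueError("channel_ids must be unique")
        if self.data.shape[0] != len(self.channel_ids):
            raise ValueError("data rows must match channel_ids")
        if not self.bad_channels <= set(self.channel_ids):
            raise ValueError("bad_channels must be a subset of channel_ids")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def epoched(self) -> bool:
        return self.data.ndim == 3

    def good_mask(self) -> np.ndarray:
        return np.array([c not in self.bad_channels for c in self.channel_ids])


@dataclass
class Epochs:
    """Z-scored high-gamma epochs: ``(electrodes, frames, trials)``.

    ``t0`` is the time of frame 0 relative to word onset; the baseline window
    is the interval used for per-trial z-scoring.
    """

    data: np.ndarray
    frame_rate: float
    t0: float
    channel_ids: list[str]
    baseline_window: tuple[float, float] = (-0.5, 0.0)

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.frame_rate


def _advance(stage: str, to: str) -> None:
    if STAGES.index(to) <= STAGES.index(stage):
        raise PipelineError(f"cannot move stage backwards: {stage} -> {to}")


def reject_channels(rec: Recording, variance_z_cutoff: float = 5.0) -> Recording:
    """Flag channels whose log-variance is an outlier on the grid.

    A channel is marked bad when its log-variance deviates from the grid
    median by more than ``variance_z_cutoff`` robust z-units (median/MAD).
    Deterministic; returns a copy with ``bad_channels`` extended.
    """
    flat = rec.data.reshape(rec.n_channels, -1)
    logv = np.log(np.var(flat, axis=1) + np.finfo(float).tiny)
    med = np.median(logv)
    mad = np.median(np.abs(logv - med))
    scale = 1.4826 * mad
    if scale == 0:
        z = np.zeros_like(logv)
    else:
        z = (logv - med) / scale
    bad = {c for c, zi in zip(rec.channel_ids, z) if abs(zi) > variance_z_cutoff}
    new_bad = rec.bad_channels | bad
    if len(new_bad) == rec.n_channels:
        raise PipelineError(
            "all channels rejected; robust z-scores: "
            + ", ".join(f"{c}={zi:.1f}" for c, zi in zip(rec.channel_ids, z))
        )
    return replace(rec, bad_channels=new_bad)


def common_average_reference(rec: Recording, electrode_table: pd.DataFrame) -> Recording:
    """Subtract the per-sample mean of the good channels in each grid row.

    ``electrode_table`` must carry ``id`` and ``row`` columns covering every
    channel.  Bad channels are excluded from the row means but are themselves
    re-referenced so the array keeps its shape.
    """
    if rec.stage != "raw":
        raise PipelineError(f"common_average_reference expects stage 'raw', got {rec.stage!r}")
    rows = electrode_table.set_index("id")["row"]
    missing = [c for c in rec.channel_ids if c not in rows.index]
    if missing:
        raise ValueError(f"channels missing from electrode table: {missing}")
    row_of = np.array([rows[c] for c in rec.channel_ids])
    good = rec.good_mask()
    out = rec.data.astype(float).copy()
    for r in np.unique(row_of):
        members = row_of == r
        contributors = members & good
        if not contributors.any():
            raise PipelineError(f"grid row {r} has no good channels to reference against")
        out[members] -= out[contributors].mean(axis=0, keepdims=True)
    return replace(rec, data=out, stage="referenced")


def design_bandpass(band: tuple[float, float], sample_rate: float,
                    transition_frac: float = 0.1) -> np.ndarray:
    """Linear-phase FIR band-pass with transition width 10% of the band edges."""
    lo, hi = band
    trans = transition_frac * lo
    numtaps = int(np.ceil(3.3 * sample_rate / trans))
    numtaps += 1 - numtaps % 2  # odd -> symmetric, integer group delay
    return scipy.signal.firwin(numtaps, [lo, hi], fs=sample_rate, pass_zero=False)


def extract_high_gamma(
    rec: Recording,
    band: tuple[float, float] = (70.0, 150.0),
    frame_rate: float = 100.0,
    transition_frac: float = 0.1,
) -> Recording:
    """Band-pass to ``band``, take the Hilbert envelope, decimate to ``frame_rate``.

    The FIR filter is symmetric (zero phase when applied centred), the analytic
    amplitude is the magnitude of the Hilbert transform, and decimation is a
    boxcar anti-alias average over each output frame, which preserves
    nonnegativity and event alignment.
    """
    if rec.stage != "referenced":
        raise PipelineError(f"extract_high_gamma expects stage 'referenced', got {rec.stage!r}")
    if band[1] >= rec.sample_rate / 2:
        raise ValueError(f"band upper edge {band[1]} Hz at/above Nyquist "
                         f"({rec.sample_rate / 2} Hz)")
    q = rec.sample_rate / frame_rate
    if abs(q - round(q)) > 1e-9:
        raise ValueError("sample_rate must be an integer multiple of frame_rate")
    q = int(round(q))

    h = design_bandpass(band, rec.sample_rate, transition_frac)
    pad = len(h) // 2
    shape = rec.data.shape
    x = rec.data.reshape(shape[0], shape[1], -1)  # (E, S, T) with T=1 if continuous
    x = np.moveaxis(x, 1, -1).reshape(-1, shape[1])  # (E*T, S)
    xp = np.pad(x, ((0, 0), (pad, pad)), mode="reflect")
    filt = scipy.signal.fftconvolve(xp, h[None, :], mode="same", axes=1)[:, pad:-pad]
    env = np.abs(scipy.signal.hilbert(filt, axis=1))
    n_frames = shape[1] // q
    env = env[:, : n_frames * q].reshape(env.shape[0], n_frames, q).mean(axis=2)
    env = env.reshape(shape[0], -1, n_frames)  # (E, trials, frames)
    env = np.moveaxis(env, 1, 2)  # (E, frames, trials)
    if rec.data.ndim == 2:
        env = env[:, :, 0]
    return replace(rec, data=env, sample_rate=frame_rate, stage="highgamma")


def epoch_and_zscore(
    rec: Recording,
    trials: pd.DataFrame,
    window: tuple[float, float] = (-0.5, 1.0),
    baseline: tuple[float, float] = (-0.5, 0.0),
    mode: str = "per_trial",
) -> Epochs:
    """Cut the analysis window and z-score each electrode/trial to its baseline.

    ``rec`` must be epoched high-gamma data whose trial axis matches the order
    of ``trials``.  With ``mode='per_trial'`` (the default) the baseline mean
    and SD are computed within each trial's own baseline window; with
    ``mode='pooled'`` baseline statistics are pooled across trials per
    electrode.
    """
    if rec.stage != "highgamma":
        raise PipelineError(f"epoch_and_zscore expects stage 'highgamma', got {rec.stage!r}")
    if not rec.epoched:
        raise ValueError("epoch_and_zscore requires epoched data")
    if rec.data.shape[2] != len(trials):
        raise ValueError("trial axis does not match the trial table")
    if mode not in ("per_trial", "pooled"):
        raise ValueError(f"unknown baseline mode {mode!r}")

    fr = rec.sample_rate
    win = frame_slice(window, fr, rec.t0)
    if win.start < 0 or win.stop > rec.data.shape[1]:
        raise ValueError(f"window {window} does not fit inside the recording")
    good = rec.good_mask()
    data = rec.data[good][:, win, :].astype(float)
    t0 = rec.t0 + win.start / fr

    base = frame_slice(baseline, fr, t0)
    if base.start < 0 or base.stop > data.shape[1]:
        raise ValueError(f"baseline {baseline} outside the epoch window {window}")
    seg = data[:, base, :]
    if mode == "per_trial":
        mu = seg.mean(axis=1, keepdims=True)
        sd = seg.std(axis=1, keepdims=True, ddof=0)
    else:
        mu = seg.mean(axis=(1, 2), keepdims=True)
        sd = seg.std(axis=(1, 2), keepdims=True, ddof=0)
    zero = np.argwhere(sd[:, 0, :] == 0)
    if zero.size:
        e, t = zero[0]
        tid = trials.iloc[int(t)].get("trial_id", int(t)) if mode == "per_trial" else "pooled"
        raise PipelineError(
            f"degenerate baseline (SD=0) on electrode "
            f"{np.array(rec.channel_ids)[good][e]}, trial {tid}"
        )
    z = (data - mu) / sd
    ids = [c for c, g in zip(rec.channel_ids, good) if g]
    return Epochs(data=z, frame_rate=fr, t0=t0, channel_ids=ids, baseline_window=baseline)
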