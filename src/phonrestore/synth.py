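"""Synthetic bistable-perception ECoG generator.

Emulates, at the spectrogram and field-potential level, the experimental
design used to study phoneme restoration: word-pair triplets that differ only
in a critical phoneme, a noise version whose critical phoneme is replaced by
RMS-matched 1/f noise, and electrode responses driven by a linear
spectrotemporal forward model embedded as amplitude modulation of a
high-gamma carrier in raw voltage.

Two effects can be planted with independent knobs:

* **restoration** -- on noise trials the neural drive is mixed toward the
  drive evoked by the *perceived* original word, starting
  ``restoration_latency`` seconds after critical-phoneme onset
  (``restoration_gain`` in [0, 1]; 0 means percept-independent responses);
* **pre-stimulus bias** -- a latent state ``b in {+1, -1}`` drawn per noise
  trial adds a slow amplitude offset on a designated (frontal-labelled)
  electrode subset during a pre-critical-phoneme window, and the reported
  percept follows the state with probability ``percept_bias_strength``.

All randomness flows from explicit ``numpy.random.Generator`` objects, so
identical configurations and seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phonrestore.preprocess import Recording
from phonrestore.times import frame_slice

REGIONS = ("STG", "MTG", "IFG", "precentral", "postcentral", "other")
FRONTAL_REGIONS = ("IFG", "precentral", "postcentral")

# overall scale of the spectrotemporal drive relative to the carrier baseline;
# gives single-trial high-gamma responses of a few baseline SDs, the magnitude
# range in which electrode-selection z thresholds of 1-2.25 are meaningful
_DRIVE_SCALE = 0.4


@dataclass
class SpectrogramTriplet:
    """Spectrograms of one word pair plus its noise-masked version.

    Power matrices are (frequency bins x time frames), arbitrary units, all
    nonnegative.  Frame 0 starts at ``word_onset`` (0 s by convention);
    ``cp_onset``/``cp_offset`` delimit the critical phoneme, half-open.
    """

    word_pair_id: str
    spec_orig1: np.ndarray
    spec_orig2: np.ndarray
    spec_noise: np.ndarray
    freqs: np.ndarray
    frame_rate: float
    word_onset: float
    cp_onset: float
    cp_offset: float

    @property
    def duration(self) -> float:
        return self.spec_orig1.shape[1] / self.frame_rate

    @property
    def word_offset(self) -> float:
        return self.word_onset + self.duration

    def cp_frames(self) -> slice:
        return frame_slice((self.cp_onset, self.cp_offset), self.frame_rate, self.word_onset)


@dataclass
class ForwardModel:
    """Linear spectrotemporal forward model plus planted-effect parameters.

    ``strf`` maps spectrogram power to per-electrode high-gamma drive
    (electrodes x frequency bins x lag frames, causal lags).  Electrodes with
    an all-zero filter (e.g. frontal bias electrodes) carry no stimulus drive.
    """

    strf: np.ndarray
    channel_ids: list[str]
    noise_sd: float = 0.3
    env_noise_sd: float = 0.3
    restoration_gain: float = 0.6
    restoration_latency: float = 0.15
    bias_electrodes: list[str] = field(default_factory=list)
    bias_amplitude: float = 0.5
    bias_window: tuple[float, float] = (-0.3, 0.0)
    carrier_freqs: np.ndarray | None = None
    baseline_level: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.restoration_gain <= 1.0:
            raise ValueError("restoration_gain must lie in [0, 1]")
        if not set(self.bias_electrodes) <= set(self.channel_ids):
            raise ValueError("bias_electrodes must be a subset of channel_ids")
        if self.strf.shape[0] != len(self.channel_ids):
            raise ValueError("strf electrode axis must match channel_ids")

    @property
    def n_electrodes(self) -> int:
        return self.strf.shape[0]


@dataclass
class SynthConfig:
    """Study-level simulation parameters.

    Defaults emulate the recording setup the analyses were designed for: a
    16 x 16 high-density grid at 4 mm pitch, voltage sampled at 1 kHz (the
    70-150 Hz band must be representable) and a 100 Hz spectrogram/analysis
    frame rate, with on the order of a dozen presentations of each stimulus
    version per word pair.
    """

    n_electrodes: int = 256
    grid_shape: tuple[int, int] = (16, 16)
    grid_pitch_mm: float = 4.0
    n_trials_per_condition: int = 12
    sample_rate: float = 1000.0
    frame_rate: float = 100.0
    percept_bias_strength: float = 0.85
    epoch_window: tuple[float, float] = (-0.7, 1.2)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_condition < 2:
            raise ValueError("n_trials_per_condition must be >= 2")
        if self.sample_rate < 4 * 150.0:
            raise ValueError("sample_rate must be >= 600 Hz so the 70-150 Hz band is representable")
        if self.grid_shape[0] * self.grid_shape[1] != self.n_electrodes:
            raise ValueError("grid_shape must multiply out to n_electrodes")
        if not 0.0 <= self.percept_bias_strength <= 1.0:
            raise ValueError("percept_bias_strength must lie in [0, 1]")


def default_freq_axis(n_bins: int = 32, lo: float = 200.0, hi: float = 8000.0) -> np.ndarray:
    """Log-spaced acoustic frequency axis in Hz."""
    return np.geomspace(lo, hi, n_bins)


def _formant_base(freqs: np.ndarray, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Speech-like base spectrogram: a few slowly moving spectral peaks."""
    logf = np.log(freqs)
    t = np.linspace(0.0, 1.0, n_frames)
    word_env = np.sin(np.pi * t) ** 0.5  # rises and falls over the word
    spec = np.full((freqs.size, n_frames), 0.05)
    for _ in range(3):
        c0 = rng.uniform(np.log(250.0), np.log(3000.0))
        drift = rng.uniform(-0.3, 0.3)
        width = rng.uniform(0.15, 0.3)
        amp = rng.uniform(0.8, 1.5)
        centers = c0 + drift * t
        spec += amp * word_env * np.exp(-0.5 * ((logf[:, None] - centers[None, :]) / width) ** 2)
    return spec


def _segment_rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def make_triplet(
    word_pair_id: str,
    freqs: np.ndarray,
    frame_rate: float,
    cp_window: tuple[float, float],
    contrast_band: tuple[float, float],
    rng: np.random.Generator,
    duration: float = 0.8,
    contrast_power: float = 2.0,
) -> SpectrogramTriplet:
    """Build a word-pair spectrogram triplet with a planted phonetic contrast.

    The two originals are identical except inside ``cp_window``: orig1 carries
    elevated power in ``contrast_band`` (a fricative-like high-frequency
    component), orig2 carries a complementary bump one octave below the band.
    The noise version replaces the whole critical-phoneme segment with
    1/f-distributed power, RMS-matched to the mean RMS of the two replaced
    segments.
    """
    cp_on, cp_off = cp_window
    if not (0.0 < cp_on < cp_off < duration):
        raise ValueError(f"cp_window {cp_window} must lie strictly inside (0, {duration})")
    band_mask = (freqs >= contrast_band[0]) & (freqs <= contrast_band[1])
    if not band_mask.any():
        raise ValueError(f"contrast_band {contrast_band} contains no frequency bins")

    n_frames = int(round(duration * frame_rate))
    base = _formant_base(freqs, n_frames, rng)
    cp = frame_slice(cp_window, frame_rate, 0.0)
    n_cp = cp.stop - cp.start
    bump_t = np.sin(np.pi * (np.arange(n_cp) + 0.5) / n_cp)  # confined to the window

    orig1 = base.copy()
    orig1[np.ix_(band_mask, range(cp.start, cp.stop))] += contrast_power * bump_t

    alt_mask = (freqs >= contrast_band[0] / 2) & (freqs < contrast_band[0])
    if not alt_mask.any():
        alt_mask = ~band_mask & (freqs < contrast_band[0])
    orig2 = base.copy()
    orig2[np.ix_(alt_mask, range(cp.start, cp.stop))] += contrast_power * bump_t

    # 1/f-distributed replacement segment, RMS-matched to the excised content
    seg_shape = (freqs.size, n_cp)
    amp = np.sqrt(1.0 / freqs)[:, None] * (
        rng.standard_normal(seg_shape) ** 2 + rng.standard_normal(seg_shape) ** 2
    )
    target = 0.5 * (_segment_rms(orig1[:, cp]) + _segment_rms(orig2[:, cp]))
    seg = amp * (target / _segment_rms(amp))
    noise = orig1.copy()
    noise[:, cp] = seg

    return SpectrogramTriplet(
        word_pair_id=word_pair_id,
        spec_orig1=orig1,
        spec_orig2=orig2,
        spec_noise=noise,
        freqs=np.asarray(freqs, dtype=float),
        frame_rate=frame_rate,
        word_onset=0.0,
        cp_onset=cp_on,
        cp_offset=cp_off,
    )


def electrode_grid(cfg: SynthConfig) -> pd.DataFrame:
    """Electrode table for the simulated grid.

    Rows in the upper quarter of the grid are labelled frontal
    (IFG/precentral/postcentral, the supra-Sylvian group), the middle half
    STG, and the rest MTG/other (sub-Sylvian).  The left half of the columns
    is hemisphere L, the right half R.
    """
    n_rows, n_cols = cfg.grid_shape
    rows, cols = np.divmod(np.arange(cfg.n_electrodes), n_cols)
    region = []
    for r in rows:
        if r < max(1, n_rows // 4):
            region.append(FRONTAL_REGIONS[r % 3])
        elif r < max(2, (3 * n_rows) // 4):
            region.append("STG")
        else:
            region.append("MTG" if r % 2 else "other")
    return pd.DataFrame(
        {
            "id": [f"e{i:03d}" for i in range(cfg.n_electrodes)],
            "row": rows,
            "col": cols,
            "x_mm": cols * cfg.grid_pitch_mm,
            "y_mm": rows * cfg.grid_pitch_mm,
            "region": region,
            "hemisphere": np.where(cols < n_cols // 2, "L", "R"),
        }
    )


def default_forward_model(
    cfg: SynthConfig,
    freqs: np.ndarray,
    electrodes: pd.DataFrame,
    rng: np.random.Generator,
    contrast_band: tuple[float, float] = (3000.0, 8000.0),
    n_contrast_electrodes: int = 12,
    n_bias_electrodes: int = 8,
    strf_lag_frames: int = 8,
    **kwargs,
) -> ForwardModel:
    """Build a forward model matching the default electrode layout.

    STG electrodes get random smooth spectrotemporal filters; a designated
    subset is tuned inside ``contrast_band`` so the planted phonetic contrast
    drives them differentially (the "effect" electrodes).  Frontal electrodes
    carry no stimulus drive; ``n_bias_electrodes`` of them (scattered across
    grid rows so row-wise re-referencing cannot cancel the signal) receive
    the pre-stimulus bias.  Remaining keyword arguments are forwarded to
    :class:`ForwardModel`.
    """
    ids = list(electrodes["id"])
    logf = np.log(freqs)
    n_lags = strf_lag_frames
    strf = np.zeros((cfg.n_electrodes, freqs.size, n_lags))

    stg_idx = np.flatnonzero(electrodes["region"].to_numpy() == "STG")
    if stg_idx.size == 0:
        raise ValueError("electrode table has no STG electrodes")
    n_contrast = min(n_contrast_electrodes, stg_idx.size)
    band_center = np.log(np.sqrt(contrast_band[0] * contrast_band[1]))
    for k, e in enumerate(stg_idx):
        if k < n_contrast:
            c = band_center + rng.uniform(-0.1, 0.1)
            width = rng.uniform(0.2, 0.35)
        else:
            c = rng.uniform(np.log(freqs[0]), np.log(contrast_band[0]))
            width = rng.uniform(0.25, 0.5)
        prof = np.exp(-0.5 * ((logf - c) / width) ** 2)
        lag = int(rng.integers(0, 3))
        kern = np.zeros(n_lags)
        kern[lag:] = 0.6 ** np.arange(n_lags - lag)  # decaying temporal integration
        w = prof[:, None] * kern[None, :]
        strf[e] = _DRIVE_SCALE * w / np.linalg.norm(w)

    frontal_idx = np.flatnonzero(electrodes["region"].isin(FRONTAL_REGIONS).to_numpy())
    bias_ids = [ids[i] for i in frontal_idx[: min(n_bias_electrodes, frontal_idx.size)]]

    carriers = rng.uniform(80.0, 140.0, size=cfg.n_electrodes)
    return ForwardModel(
        strf=strf,
        channel_ids=ids,
        bias_electrodes=bias_ids,
        carrier_freqs=carriers,
        **kwargs,
    )


def _drive_from_spec(fm: ForwardModel, spec: np.ndarray, n_frames: int, onset_frame: int) -> np.ndarray:
    """STRF convolution of a spectrogram placed on the epoch frame axis."""
    norm = _segment_rms(spec)
    s = spec / norm if norm > 0 else spec
    e_, f_, n_lags = fm.strf.shape
    drive = np.zeros((e_, n_frames))
    t_len = s.shape[1]
    for lag in range(n_lags):
        start = onset_frame + lag
        stop = min(start + t_len, n_frames)
        if stop <= start:
            continue
        drive[:, start:stop] += np.einsum("ef,ft->et", fm.strf[:, :, lag], s[:, : stop - start])
    return drive


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sigma_frames: float) -> np.ndarray:
    """Unit-variance Gaussian noise smoothed along the last axis."""
    import scipy.ndimage

    x = scipy.ndimage.gaussian_filter1d(
        rng.standard_normal(shape), sigma_frames, axis=-1, mode="reflect"
    )
    # analytic SD of white noise after Gaussian smoothing: ||kernel||_2
    return x * np.sqrt(2.0 * np.sqrt(np.pi) * sigma_frames)


def _bias_profile(fm: ForwardModel, times: np.ndarray, cp_onset: float) -> np.ndarray:
    """Raised-cosine bias waveform over the bias window (relative to cp onset)."""
    b0, b1 = fm.bias_window
    lo, hi = cp_onset + b0, cp_onset + b1
    w = np.zeros_like(times)
    inside = (times >= lo) & (times < hi)
    w[inside] = 0.5 * (1 - np.cos(2 * np.pi * (times[inside] - lo) / (hi - lo)))
    return w


def simulate_recording(
    triplets: list[SpectrogramTriplet],
    fm: ForwardModel,
    cfg: SynthConfig,
) -> tuple[Recording, pd.DataFrame]:
    """Simulate epoched raw-voltage trials for every triplet and condition.

    Each trial's per-electrode high-gamma drive is the STRF convolution of the
    trial's spectrogram; on noise trials a latent bias state is drawn, the
    reported percept follows it with probability
    ``cfg.percept_bias_strength``, the bias adds a slow amplitude offset on
    the bias electrodes during the bias window, and after
    ``cp_onset + restoration_latency`` the drive is mixed toward the
    perceived original's drive with weight ``restoration_gain``.  The drive
    amplitude-modulates a per-electrode carrier in the 70-150 Hz band, plus
    broadband white noise, to form raw voltage.

    Returns the epoched raw :class:`Recording` (electrodes x samples x
    trials) and the trial table.
    """
    for tr in triplets:
        if tr.freqs.size != fm.strf.shape[1]:
            raise ValueError(
                f"triplet {tr.word_pair_id!r} has {tr.freqs.size} frequency bins, "
                f"forward model expects {fm.strf.shape[1]}"
            )
    rng = np.random.default_rng(cfg.rng_seed)
    fr = cfg.frame_rate
    t_lo, t_hi = cfg.epoch_window
    n_frames = int(round((t_hi - t_lo) * fr))
    n_samples = int(round((t_hi - t_lo) * cfg.sample_rate))
    frame_times = t_lo + np.arange(n_frames) / fr
    sample_times = t_lo + np.arange(n_samples) / cfg.sample_rate
    onset_frame = int(round((0.0 - t_lo) * fr))
    n_e = fm.n_electrodes
    if fm.carrier_freqs is None:
        carrier_freqs = np.linspace(80.0, 140.0, n_e)
    else:
        carrier_freqs = np.asarray(fm.carrier_freqs)
    bias_idx = np.array([fm.channel_ids.index(c) for c in fm.bias_electrodes], dtype=int)

    records = []
    voltages = []
    trial_id = 0
    for tr in triplets:
        drives = {
            "orig1": _drive_from_spec(fm, tr.spec_orig1, n_frames, onset_frame),
            "orig2": _drive_from_spec(fm, tr.spec_orig2, n_frames, onset_frame),
            "noise": _drive_from_spec(fm, tr.spec_noise, n_frames, onset_frame),
        }
        mix_mask = frame_times >= tr.cp_onset + fm.restoration_latency
        bias_wave = _bias_profile(fm, frame_times, tr.cp_onset)
        for cond in ("orig1", "orig2", "noise"):
            for _ in range(cfg.n_trials_per_condition):
                if cond == "noise":
                    b = int(rng.choice([1, -1]))
                    favoured = 1 if b > 0 else 2
                    if rng.random() < cfg.percept_bias_strength:
                        percept = favoured
                    else:
                        percept = 3 - favoured
                    drive = drives["noise"].copy()
                    g = fm.restoration_gain
                    perc_drive = drives[f"orig{percept}"]
                    drive[:, mix_mask] = (
                        (1 - g) * drive[:, mix_mask] + g * perc_drive[:, mix_mask]
                    )
                    if bias_idx.size:
                        drive[bias_idx] += b * fm.bias_amplitude * bias_wave
                else:
                    b = 0
                    percept = 1 if cond == "orig1" else 2
                    drive = drives[cond]
                # ongoing background high-gamma fluctuation: smooth amplitude
                # noise so baseline SDs are realistic (not carrier-flat)
                bg = _smooth_noise(rng, (n_e, n_frames), sigma_frames=2.0) * fm.env_noise_sd
                modulator = np.clip(
                    fm.baseline_level
                    + np.stack(
                        [
                            np.interp(sample_times, frame_times, drive[e] + bg[e])
                            for e in range(n_e)
                        ]
                    ),
                    0.05,
                    None,
                )
                phases = rng.uniform(0, 2 * np.pi, size=n_e)
                carrier = np.sin(
                    2 * np.pi * carrier_freqs[:, None] * sample_times[None, :] + phases[:, None]
                )
                v = modulator * carrier + fm.noise_sd * rng.standard_normal((n_e, n_samples))
                voltages.append(v)
                records.append(
                    {
                        "trial_id": trial_id,
                        "word_pair_id": tr.word_pair_id,
                        "condition": cond,
                        "reported_percept": percept,
                        "bias_state_truth": b,
                        "word_onset_s": 0.0,
                        "cp_onset_s": tr.cp_onset,
                        "cp_offset_s": tr.cp_offset,
                        "word_offset_s": tr.word_offset,
                    }
                )
                trial_id += 1

    data = np.stack(voltages, axis=2)  # (E, samples, trials)
    rec = Recording(
        data=data,
        sample_rate=cfg.sample_rate,
        stage="raw",
        channel_ids=list(fm.channel_ids),
        t0=t_lo,
    )
    return rec, pd.DataFrame(records)


def make_training_corpus(
    fm: ForwardModel,
    duration_s: float,
    rng: np.random.Generator,
    freqs: np.ndarray | None = None,
    frame_rate: float = 100.0,
) -> tuple[Recording, np.ndarray]:
    """Continuous speech-like corpus and the forward-model high-gamma response.

    The spectrogram is band-limited modulated noise with a 2-8 Hz envelope
    rhythm (the syllabic rate of natural speech) and a 1/f spectral profile.
    The returned :class:`Recording` is at the ``highgamma`` stage (drive plus
    ``fm.noise_sd`` white noise at the frame rate) and is intended only for
    fitting reconstruction filters, mirroring decoder training on separate
    passive-listening sessions.
    """
    if duration_s < 60:
        raise ValueError("duration_s must be >= 60 to fit lagged filters")
    if freqs is None:
        freqs = default_freq_axis(fm.strf.shape[1])
    if freqs.size != fm.strf.shape[1]:
        raise ValueError("freqs must match the forward model's frequency axis")
    n_frames = int(round(duration_s * frame_rate))

    import scipy.signal

    sos = scipy.signal.butter(2, [2.0, 8.0], btype="bandpass", fs=frame_rate, output="sos")
    mod = scipy.signal.sosfiltfilt(sos, rng.standard_normal((freqs.size, n_frames)), axis=1)
    mod = np.clip(1.0 + 2.0 * mod / mod.std(axis=1, keepdims=True) * 0.5, 0.0, None)
    profile = (1.0 / freqs) ** 0.5
    spec = profile[:, None] * mod

    drive = _drive_from_spec(fm, spec, n_frames, 0)
    resp = drive + fm.noise_sd * rng.standard_normal(drive.shape)
    rec = Recording(
        data=resp,
        sample_rate=frame_rate,
        stage="highgamma",
        channel_ids=list(fm.channel_ids),
        t0=0.0,
    )
    return rec, spec
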