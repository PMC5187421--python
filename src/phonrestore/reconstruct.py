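"""Linear stimulus-spectrogram reconstruction from neural population activity.

Decoding filters map lagged multi-electrode high-gamma responses (lags -300
to 0 ms: the response *follows* the stimulus, so reconstruction at time t
consumes responses from t to t+300 ms) onto each spectrogram frequency band,
fit by ridge regression on a separate training corpus, optionally with the
penalty chosen by blocked cross-validation.  Reconstructions of the word
triplets are compared via 2D (flattened Pearson) correlations and via
Euclidean distances between critical-phoneme power spectra restricted to the
frequency bins that best discriminate the two originals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from phonrestore.preprocess import Epochs, Recording
from phonrestore.synth import SpectrogramTriplet
from phonrestore.times import frame_slice

GROUPS = ("orig1", "orig2", "noise_p1", "noise_p2")
#: (same-percept, cross-percept) reconstruction pairings
SAME_PAIRS = (("orig1", "noise_p1"), ("orig2", "noise_p2"))
CROSS_PAIRS = (("orig1", "noise_p2"), ("orig2", "noise_p1"))


@dataclass
class DecoderFilters:
    """Lagged linear decoding filters: (frequency bins x electrodes x lags)."""

    g: np.ndarray
    lags: np.ndarray  # seconds, -0.3 .. 0
    ridge_penalty: float
    channel_ids: list[str]
    frame_rate: float
    intercept: np.ndarray  # per-frequency
    resp_mean: np.ndarray  # per-electrode standardization of the training corpus
    resp_sd: np.ndarray
    cv_r: np.ndarray | None = None  # per-frequency cross-validated correlation

    @property
    def n_lags(self) -> int:
        return self.g.shape[2]


@dataclass
class ReconstructionReport:
    """Reconstructed spectrograms per group plus fidelity metrics."""

    recons: dict[str, np.ndarray]  # group -> (freq x epoch frames)
    frame_rate: float
    t0: float
    freqs: np.ndarray
    corr: pd.DataFrame | None = None
    disc_bins: np.ndarray | None = None
    spectra: dict[str, np.ndarray] = field(default_factory=dict)
    distances: dict[tuple[str, str], float] = field(default_factory=dict)
    u_stat: float | None = None
    u_p: float | None = None


def _lagged_design(resp: np.ndarray, n_lags: int) -> np.ndarray:
    """Design matrix of future-response copies.

    ``resp`` is (electrodes, frames); column block k holds the response
    shifted so that row t sees R[:, t + k], k = 0 .. n_lags-1 (zero-padded
    past the end).  Shape: (frames, electrodes * n_lags).
    """
    n_e, n_t = resp.shape
    x = np.zeros((n_t, n_e, n_lags))
    for k in range(n_lags):
        x[: n_t - k, :, k] = resp[:, k:].T
    return x.reshape(n_t, n_e * n_lags)


def fit_decoder(
    train_resp: Recording,
    train_spec: np.ndarray,
    lags: tuple[float, float] = (-0.3, 0.0),
    ridge_penalty: float | str = "cv",
    n_folds: int = 5,
    penalty_grid: np.ndarray | None = None,
) -> DecoderFilters:
    """Fit per-frequency ridge filters on a continuous training corpus.

    ``train_resp`` must be a continuous high-gamma :class:`Recording` aligned
    frame-by-frame with ``train_spec`` (freq x frames).  Responses are
    z-scored per electrode with the corpus statistics (the same scale as the
    baseline-z-scored epochs the filters are later applied to).  With
    ``ridge_penalty='cv'`` the penalty is chosen on a log grid by blocked
    cross-validated mean correlation across frequency bands.
    """
    if train_resp.stage != "highgamma":
        raise ValueError("decoder training expects a highgamma-stage recording")
    resp = train_resp.data
    if resp.ndim != 2:
        raise ValueError("training response must be continuous (electrodes x frames)")
    if resp.shape[1] != train_spec.shape[1]:
        raise ValueError("response and spectrogram frame counts differ")
    fr = train_resp.sample_rate
    n_lags = int(round((lags[1] - lags[0]) * fr)) + 1
    n_e = resp.shape[0]
    p = n_e * n_lags
    if resp.shape[1] < 10 * p / 1.0:
        warnings.warn("training corpus is short relative to the number of lagged features")

    mu = resp.mean(axis=1)
    sd = resp.std(axis=1)
    sd = np.where(sd == 0, 1.0, sd)
    rz = (resp - mu[:, None]) / sd[:, None]
    x = _lagged_design(rz, n_lags)
    y = train_spec.T - train_spec.mean(axis=1)  # (frames, freq), centred
    intercept = train_spec.mean(axis=1)

    # The lagged design is typically rank-deficient (smooth envelopes make
    # neighbouring lag copies nearly collinear) and the informative
    # deconvolution directions can sit many orders of magnitude below the top
    # singular value, so ridge is solved through an SVD of X itself: one SVD
    # per fold, cheap reuse across the penalty grid, and a pseudoinverse-like
    # limit as the penalty goes to zero.
    def svd_solve(xmat, ymat):
        u, s, vt = scipy.linalg.svd(xmat, full_matrices=False)
        return s, vt, u.T @ ymat

    def ridge_w(s, vt, uty, lam):
        if lam == 0.0:
            cutoff = np.finfo(float).eps * max(vt.shape[1], uty.shape[0]) * s[0]
            fac = np.where(s > cutoff, 1.0 / np.where(s > cutoff, s, 1.0), 0.0)
        else:
            fac = s / (s**2 + lam)
        return vt.T @ (fac[:, None] * uty)

    cv_r = None
    if ridge_penalty == "cv":
        s_full, vt_full, uty_full = svd_solve(x, y)
        if penalty_grid is None:
            penalty_grid = s_full[0] ** 2 * np.logspace(-14, 0, 8)
        bounds = np.linspace(0, x.shape[0], n_folds + 1).astype(int)
        scores = np.zeros(len(penalty_grid))
        per_freq = np.zeros((len(penalty_grid), y.shape[1]))
        for f0, f1 in zip(bounds[:-1], bounds[1:]):
            xv, yv = x[f0:f1], y[f0:f1]
            mask = np.ones(x.shape[0], dtype=bool)
            mask[f0:f1] = False
            s_tr, vt_tr, uty_tr = svd_solve(x[mask], y[mask])
            for i, lam in enumerate(penalty_grid):
                pred = xv @ ridge_w(s_tr, vt_tr, uty_tr, lam)
                r = _columnwise_corr(pred, yv)
                per_freq[i] += np.nan_to_num(r)
                scores[i] += np.nanmean(r)
        best = int(np.argmax(scores))
        lam = float(penalty_grid[best])
        cv_r = per_freq[best] / n_folds
        w = ridge_w(s_full, vt_full, uty_full, lam)
    else:
        lam = float(ridge_penalty)
        if lam < 0:
            raise ValueError("ridge_penalty must be >= 0")
        s_full, vt_full, uty_full = svd_solve(x, y)
        if lam == 0 and s_full[0] == 0:
            raise np.linalg.LinAlgError(
                "lagged design is numerically singular; use a positive ridge penalty"
            )
        w = ridge_w(s_full, vt_full, uty_full, lam)
    g = w.T.reshape(y.shape[1], n_e, n_lags)
    return DecoderFilters(
        g=g,
        lags=np.linspace(lags[1], lags[0], n_lags),  # lag of design block k is -k/fr
        ridge_penalty=lam,
        channel_ids=list(train_resp.channel_ids),
        frame_rate=fr,
        intercept=intercept,
        resp_mean=mu,
        resp_sd=sd,
        cv_r=cv_r,
    )


def _columnwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    num = (ac * bc).sum(axis=0)
    den = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def apply_decoder(
    filters: DecoderFilters,
    resp: np.ndarray,
    standardize: bool = True,
    add_intercept: bool = True,
) -> np.ndarray:
    """Reconstruct a spectrogram (freq x frames) from a response (elec x frames).

    ``standardize=True`` z-scores the input with the training-corpus
    statistics (use for corpus-scale responses); pass ``False`` for epoch
    data that is already baseline z-scored to the same unit scale.
    ``add_intercept=False`` omits the corpus-mean spectrum, leaving a
    centred reconstruction that carries only stimulus-driven structure.
    """
    n_f, n_e, n_lags = filters.g.shape
    if resp.shape[0] != n_e:
        raise ValueError("electrode axis does not match the decoder")
    if standardize:
        resp = (resp - filters.resp_mean[:, None]) / filters.resp_sd[:, None]
    x = _lagged_design(resp, n_lags)
    w = filters.g.reshape(n_f, n_e * n_lags).T
    out = (x @ w).T
    if add_intercept:
        out = out + filters.intercept[:, None]
    return out


def reconstruct(
    filters: DecoderFilters,
    ep: Epochs,
    trials: pd.DataFrame,
    word_pair_id: str,
    groupby: str = "percept",
    on: str = "mean",
) -> ReconstructionReport:
    """Reconstruct spectrograms per condition/percept group.

    With ``groupby='percept'`` noise trials are split by the reported percept
    (groups ``orig1, orig2, noise_p1, noise_p2``); with ``'condition'`` the
    noise trials form a single group.  ``on='mean'`` reconstructs from the
    trial-mean response; ``on='single_trial'`` averages single-trial
    reconstructions (identical for a linear decoder up to the shared
    intercept, provided for parity with trial-level analyses).
    """
    if on not in ("mean", "single_trial"):
        raise ValueError(f"unknown mode {on!r}")
    chan_idx = [ep.channel_ids.index(c) for c in filters.channel_ids]
    data = ep.data[chan_idx]
    wp_mask = (trials["word_pair_id"] == word_pair_id).to_numpy()

    if groupby == "percept":
        group_defs = {
            "orig1": wp_mask & (trials["condition"] == "orig1").to_numpy(),
            "orig2": wp_mask & (trials["condition"] == "orig2").to_numpy(),
            "noise_p1": wp_mask
            & (trials["condition"] == "noise").to_numpy()
            & (trials["reported_percept"] == 1).to_numpy(),
            "noise_p2": wp_mask
            & (trials["condition"] == "noise").to_numpy()
            & (trials["reported_percept"] == 2).to_numpy(),
        }
    elif groupby == "condition":
        group_defs = {
            c: wp_mask & (trials["condition"] == c).to_numpy()
            for c in ("orig1", "orig2", "noise")
        }
    else:
        raise ValueError(f"unknown groupby {groupby!r}")

    recons: dict[str, np.ndarray] = {}
    for name, mask in group_defs.items():
        if mask.sum() == 0:
            warnings.warn(f"group {name!r} has zero trials; omitted")
            continue
        if on == "mean":
            recons[name] = apply_decoder(filters, data[:, :, mask].mean(axis=2),
                                         standardize=False, add_intercept=False)
        else:
            per_trial = [apply_decoder(filters, data[:, :, i], standardize=False,
                                       add_intercept=False)
                         for i in np.flatnonzero(mask)]
            recons[name] = np.mean(per_trial, axis=0)
    return ReconstructionReport(
        recons=recons,
        frame_rate=ep.frame_rate,
        t0=ep.t0,
        freqs=np.array([]),
    )


def quantify(
    report: ReconstructionReport,
    triplet: SpectrogramTriplet,
    percentile: float = 90.0,
) -> ReconstructionReport:
    """Fill in fidelity metrics for one word pair's reconstructions.

    * pairwise 2D correlations (Pearson on the flattened matrices) over the
      word's time support;
    * discriminative frequency set: bins whose |orig1 - orig2|
      critical-phoneme power difference (on the *true* spectrograms) is at
      or above the given percentile across bins (ties included);
    * per-group critical-phoneme power spectra and Euclidean distances
      between them on the discriminative set.

    Reconstructions are centred (stimulus-driven structure only), so all
    metrics are computed on the linear scale.  The Mann-Whitney U test
    across word pairs is computed by :func:`compare_distances_across_pairs`
    once >= 2 pairs are available.
    """
    report.freqs = triplet.freqs
    word_sl = frame_slice((triplet.word_onset, triplet.word_offset),
                          report.frame_rate, report.t0)
    cp_sl = frame_slice((triplet.cp_onset, triplet.cp_offset), report.frame_rate, report.t0)

    names = [g for g in GROUPS if g in report.recons]
    logs = {g: report.recons[g][:, word_sl] for g in names}
    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            r = float(np.corrcoef(logs[a].ravel(), logs[b].ravel())[0, 1])
            corr.loc[a, b] = corr.loc[b, a] = r
    report.corr = corr

    cp_true = frame_slice((triplet.cp_onset, triplet.cp_offset),
                          triplet.frame_rate, triplet.word_onset)
    diff = np.abs(
        triplet.spec_orig1[:, cp_true].mean(axis=1)
        - triplet.spec_orig2[:, cp_true].mean(axis=1)
    )
    thr = np.percentile(diff, percentile)
    report.disc_bins = diff >= thr
    if not report.disc_bins.any():  # all-tied degenerate case
        report.disc_bins = np.ones_like(diff, dtype=bool)

    for g in names:
        report.spectra[g] = report.recons[g][:, cp_sl].mean(axis=1)
    report.distances = {}
    for pair in SAME_PAIRS + CROSS_PAIRS:
        a, b = pair
        if a in report.spectra and b in report.spectra:
            report.distances[pair] = float(
                np.linalg.norm(
                    report.spectra[a][report.disc_bins] - report.spectra[b][report.disc_bins]
                )
            )
    return report


def compare_distances_across_pairs(
    reports: list[ReconstructionReport],
) -> tuple[float | None, float | None]:
    """Two-sided Mann-Whitney U comparing same- vs cross-percept distances.

    Each word pair contributes its same-percept and cross-percept
    critical-phoneme spectral distances.  With fewer than two word pairs the
    test is skipped (returns ``(None, None)``) with a warning.
    """
    same = [r.distances[p] for r in reports for p in SAME_PAIRS if p in r.distances]
    cross = [r.distances[p] for r in reports for p in CROSS_PAIRS if p in r.distances]
    if len(reports) < 2:
        warnings.warn("fewer than 2 word pairs; Mann-Whitney U test skipped")
        return None, None
    if np.ptp(same + cross) == 0:
        warnings.warn("degenerate (all-equal) distances; Mann-Whitney U test skipped")
        return None, None
    res = scipy.stats.mannwhitneyu(same, cross, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def region_restricted_reconstruction(
    train_resp: Recording,
    train_spec: np.ndarray,
    ep: Epochs,
    trials: pd.DataFrame,
    word_pair_id: str,
    triplet: SpectrogramTriplet,
    electrode_table: pd.DataFrame,
    regions: set[str] | list[str],
    ridge_penalty: float | str = "cv",
    lags: tuple[float, float] = (-0.3, 0.0),
) -> ReconstructionReport:
    """Full fit -> reconstruct -> quantify path on a region-restricted set."""
    regions = set(regions)
    keep_ids = set(electrode_table.loc[electrode_table["region"].isin(regions), "id"])
    idx = [i for i, c in enumerate(train_resp.channel_ids) if c in keep_ids and c in ep.channel_ids]
    if not idx:
        raise ValueError(f"no electrodes in regions {sorted(regions)}")
    sub = Recording(
        data=train_resp.data[idx],
        sample_rate=train_resp.sample_rate,
        stage=train_resp.stage,
        channel_ids=[train_resp.channel_ids[i] for i in idx],
        t0=train_resp.t0,
    )
    filters = fit_decoder(sub, train_spec, lags=lags, ridge_penalty=ridge_penalty)
    report = reconstruct(filters, ep, trials, word_pair_id)
    return quantify(report, triplet)


def corr2d(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two flattened matrices."""
    return float(np.corrcoef(np.ravel(a), np.ravel(b))[0, 1])
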