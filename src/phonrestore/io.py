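"""On-disk dataset layout.

Arrays live in HDF5, tables in TSV:

* ``recording.h5`` -- ``/voltage`` (electrodes x samples x trials, or a
  continuous 2-D array), optionally ``/highgamma``; attributes
  ``sample_rate``, ``t0``, ``stage``, ``channel_ids``, ``bad_channels``.
* ``spectrograms.h5`` -- ``/<word_pair_id>/{orig1,orig2,noise}``, ``/freqs``,
  per-group attributes for the critical-phoneme window; root attribute
  ``frame_rate``.
* ``electrodes.tsv`` / ``trials.tsv`` -- plain pandas TSV round-trips.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from phonrestore.preprocess import Recording
from phonrestore.synth import SpectrogramTriplet


def save_recording(path: str | Path, rec: Recording, name: str = "voltage") -> None:
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        d = f.create_dataset(name, data=rec.data)
        d.attrs["sample_rate"] = rec.sample_rate
        d.attrs["stage"] = rec.stage
        d.attrs["t0"] = rec.t0
        d.attrs["channel_ids"] = [c.encode() for c in rec.channel_ids]
        d.attrs["bad_channels"] = [c.encode() for c in sorted(rec.bad_channels)]


def load_recording(path: str | Path, name: str = "voltage") -> Recording:
    with h5py.File(path, "r") as f:
        d = f[name]
        def as_str(v):
            return v.decode() if isinstance(v, bytes) else str(v)

        return Recording(
            data=d[()],
            sample_rate=float(d.attrs["sample_rate"]),
            stage=str(d.attrs["stage"]),
            channel_ids=[as_str(c) for c in d.attrs["channel_ids"]],
            bad_channels={as_str(c) for c in d.attrs["bad_channels"]},
            t0=float(d.attrs["t0"]),
        )


def save_triplets(path: str | Path, triplets: list[SpectrogramTriplet]) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["frame_rate"] = triplets[0].frame_rate
        f.create_dataset("freqs", data=triplets[0].freqs)
        for tr in triplets:
            g = f.create_group(tr.word_pair_id)
            for name in ("orig1", "orig2", "noise"):
                g.create_dataset(name, data=getattr(tr, f"spec_{name}"))
            g.attrs["word_onset"] = tr.word_onset
            g.attrs["cp_onset"] = tr.cp_onset
            g.attrs["cp_offset"] = tr.cp_offset


def load_triplets(path: str | Path) -> list[SpectrogramTriplet]:
    out = []
    with h5py.File(path, "r") as f:
        freqs = f["freqs"][()]
        fr = float(f.attrs["frame_rate"])
        for wp in f:
            if wp == "freqs":
                continue
            g = f[wp]
            out.append(
                SpectrogramTriplet(
                    word_pair_id=wp,
                    spec_orig1=g["orig1"][()],
                    spec_orig2=g["orig2"][()],
                    spec_noise=g["noise"][()],
                    freqs=freqs,
                    frame_rate=fr,
                    word_onset=float(g.attrs["word_onset"]),
                    cp_onset=float(g.attrs["cp_onset"]),
                    cp_offset=float(g.attrs["cp_offset"]),
                )
            )
    return out


def save_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_ri_result(path: str | Path, res, group) -> None:
    """Write RI traces and group statistics (``ri_result.h5``)."""
    with h5py.File(path, "w") as f:
        for name in ("ri", "d0", "d1", "d2", "abs_dri"):
            f.create_dataset(name, data=getattr(res, name))
        f.attrs["word_pair_id"] = res.word_pair_id
        f.attrs["frame_rate"] = res.frame_rate
        f.attrs["t0"] = res.t0
        f.attrs["cp_onset"] = res.cp_onset
        f.attrs["channel_ids"] = [c.encode() for c in res.channel_ids]
        g = f.create_group("group")
        for name in ("times", "mean", "tstat", "p", "q"):
            g.create_dataset(name, data=getattr(group, name))
        g.create_dataset("sig", data=group.sig.astype(np.uint8))


def save_decoder(path: str | Path, filters) -> None:
    """Write decoding filters (``decoder.h5``: /g, /lags, /penalty)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("g", data=filters.g)
        f.create_dataset("lags", data=filters.lags)
        f.create_dataset("penalty", data=filters.ridge_penalty)
        f.create_dataset("intercept", data=filters.intercept)
        f.create_dataset("resp_mean", data=filters.resp_mean)
        f.create_dataset("resp_sd", data=filters.resp_sd)
        f.attrs["frame_rate"] = filters.frame_rate
        f.attrs["channel_ids"] = [c.encode() for c in filters.channel_ids]


def save_state_space(path: str | Path, ss) -> None:
    """Write the PCA state space (``state_space.h5``)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("components", data=ss.components)
        f.create_dataset("scores", data=ss.scores)
        f.create_dataset("explained_variance_ratio", data=ss.explained_variance_ratio)
        f.attrs["frame_rate"] = ss.frame_rate
        f.attrs["t0"] = ss.t0
        f.attrs["channel_ids"] = [c.encode() for c in ss.channel_ids]
        g = f.create_group("condition_means")
        for label, traj in ss.condition_means.items():
            g.create_dataset(label, data=traj)


def save_classify_result(path: str | Path, tc_orig, tc_noise,
                         generalization: np.ndarray | None = None) -> None:
    """Write accuracy timecourses and weights (``classify_result.h5``)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("accuracy_orig", data=tc_orig.accuracy)
        f.create_dataset("accuracy_noise", data=tc_noise.accuracy)
        f.create_dataset("weights_orig", data=tc_orig.weights)
        f.create_dataset("weights_noise", data=tc_noise.weights)
        f.create_dataset("times", data=tc_orig.times)
        if generalization is not None:
            f.create_dataset("generalization", data=generalization)
        f.attrs["window_len"] = tc_orig.window_len
        f.attrs["channel_ids"] = [c.encode() for c in tc_orig.channel_ids]


def save_dataset(
    out_dir: str | Path,
    rec: Recording,
    trials: pd.DataFrame,
    electrodes: pd.DataFrame,
    triplets: list[SpectrogramTriplet],
) -> None:
    """Write the full dataset layout into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec_path = out / "recording.h5"
    if rec_path.exists():
        rec_path.unlink()
    save_recording(rec_path, rec, name="voltage" if rec.stage == "raw" else rec.stage)
    save_triplets(out / "spectrograms.h5", triplets)
    save_table(out / "trials.tsv", trials)
    save_table(out / "electrodes.tsv", electrodes)


def load_dataset(in_dir: str | Path):
    """Read the dataset layout; returns (recording, trials, electrodes, triplets)."""
    d = Path(in_dir)
    with h5py.File(d / "recording.h5", "r") as f:
        name = "voltage" if "voltage" in f else list(f.keys())[0]
    rec = load_recording(d / "recording.h5", name=name)
    trials = load_table(d / "trials.tsv")
    electrodes = load_table(d / "electrodes.tsv")
    triplets = load_triplets(d / "spectrograms.h5")
    return rec, trials, electrodes, triplets
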