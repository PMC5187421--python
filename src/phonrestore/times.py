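"""Centralized time/frame conversions.

Conventions used throughout the package:

* All analysis times are in seconds **relative to word onset** (word onset = 0).
* Frame intervals are half-open: frame ``k`` of a signal whose first frame
  starts at ``t0`` covers ``[t0 + k/rate, t0 + (k+1)/rate)``.
* Frame index 0 is the first sample of the epoch window.
"""

from __future__ import annotations

import numpy as np

#: tolerance used when snapping a time to a frame edge
_EDGE_EPS = 1e-9


def time_to_frame(t: float, rate: float, t0: float = 0.0) -> int:
    """Index of the frame containing time ``t`` (half-open frames)."""
    return int(np.floor((t - t0) * rate + _EDGE_EPS))


def frame_to_time(k: int | np.ndarray, rate: float, t0: float = 0.0):
    """Start time of frame ``k``."""
    return t0 + np.asarray(k) / rate


def frame_slice(window: tuple[float, float], rate: float, t0: float = 0.0) -> slice:
    """Half-open frame slice covering the time window ``[start, stop)``."""
    start, stop = window
    if stop <= start:
        raise ValueError(f"empty time window {window!r}")
    return slice(time_to_frame(start, rate, t0), time_to_frame(stop, rate, t0))


def frame_times(n: int, rate: float, t0: float = 0.0) -> np.ndarray:
    """Start times of ``n`` consecutive frames."""
    return t0 + np.arange(n) / rate
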