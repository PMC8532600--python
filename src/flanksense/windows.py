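"""Magnitude channel and sliding-window segmentation.

The observation unit of the analysis is a fixed window of 40 consecutive
5 Hz samples (8 s), advanced by a 13-sample stride, on the stream that
remains after ambiguous samples are dropped.  A candidate window is kept
only if all 40 samples agree on a single, unambiguous label for the mode
under study (posture or behavior); windows straddling a label change are
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .io import AMBIGUOUS

WINDOW_LEN = 40
STRIDE = 13

CHANNELS = ("x", "y", "z", "amag")


def add_magnitude(trace: pd.DataFrame) -> pd.DataFrame:
    """Append the acceleration magnitude channel ``amag = sqrt(x²+y²+z²)``."""
    out = trace.copy()
    out["amag"] = np.sqrt(out["x"] ** 2 + out["y"] ** 2 + out["z"] ** 2)
    return out


def candidate_count(n_samples: int, window_len: int = WINDOW_LEN, stride: int = STRIDE) -> int:
    """Number of stride-aligned windows fully contained in ``n_samples``."""
    if n_samples < window_len:
        return 0
    return (n_samples - window_len) // stride + 1


def nominal_row_count(n_samples: int, stride: int = STRIDE) -> int:
    """The ``N // stride`` shorthand row count.

    The conventional back-of-envelope dataset size for a stride-13 sliding
    window; it overstates :func:`candidate_count` by up to
    ``(window_len - 1) // stride`` windows at the end of the stream.
    """
    return n_samples // stride


@dataclass
class WindowSet:
    """Stacked windows for one mode.

    values
        Array of shape ``(n_windows, window_len, 4)`` over channels
        ``(x, y, z, amag)``.
    labels
        One resolved label per window for the requested mode.
    start_indices
        Position of each window's first sample in the source trace.
    """

    values: np.ndarray
    labels: np.ndarray
    start_indices: np.ndarray
    mode: str
    window_len: int = WINDOW_LEN
    stride: int = STRIDE

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class SegmentReport:
    candidates: int
    retained: int
    excluded: int


def segment(
    trace: pd.DataFrame,
    mode: str,
    window_len: int = WINDOW_LEN,
    stride: int = STRIDE,
) -> tuple[WindowSet, SegmentReport]:
    """Cut a labeled trace into uniform-label windows.

    Candidate windows start at indices ``0, stride, 2*stride, …`` while
    ``start + window_len <= len(trace)``.  A candidate is retained only if
    every sample shares one non-ambiguous label for ``mode``.  A trace
    shorter than one window yields an empty set, not an error.
    """
    if mode not in ("posture", "behavior"):
        raise ValueError(f"mode must be 'posture' or 'behavior', got {mode!r}")
    if "amag" not in trace.columns:
        trace = add_magnitude(trace)

    n = len(trace)
    n_cand = candidate_count(n, window_len, stride)
    if n_cand == 0:
        empty = WindowSet(
            values=np.empty((0, window_len, len(CHANNELS))),
            labels=np.empty(0, object),
            start_indices=np.empty(0, int),
            mode=mode,
            window_len=window_len,
            stride=stride,
        )
        return empty, SegmentReport(0, 0, 0)

    starts = np.arange(n_cand) * stride
    labels = trace[mode].to_numpy(object)
    lab_win = sliding_window_view(labels, window_len)[starts]  # (n_cand, window_len)
    uniform = (lab_win == lab_win[:, :1]).all(axis=1) & (lab_win[:, 0] != AMBIGUOUS)

    data = trace[list(CHANNELS)].to_numpy(float)
    win = sliding_window_view(data, window_len, axis=0)[starts]  # (n_cand, 4, window_len)
    win = np.swapaxes(win, 1, 2)

    ws = WindowSet(
        values=win[uniform].copy(),
        labels=lab_win[uniform, 0].copy(),
        start_indices=starts[uniform],
        mode=mode,
        window_len=window_len,
        stride=stride,
    )
    retained = int(uniform.sum())
    return ws, SegmentReport(candidates=n_cand, retained=retained, excluded=n_cand - retained)
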