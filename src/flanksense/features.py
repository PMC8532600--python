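"""Per-window signal statistics.

Nine statistics per channel (x, y, z, amag) give the 36-variable feature
vector of each 8 s window:

========  ======================================================
avg       arithmetic mean
sd        sample standard deviation (n−1)
zc        zero crossings of the mean-centered signal
p2p       peak-to-peak (max − min)
rms       root mean square
kur       excess kurtosis (moment estimator; Gaussian → 0)
skw       skewness (moment estimator)
cf        crest factor, max|w| / rms
Vrms      RMS of the running sum (discrete integral, zero initial
          condition, no Δt factor; units g·sample)
========  ======================================================

Conventions that the source statistics' names leave open are fixed here:
``zc`` counts sign changes after mean-centering (without removing the ~1 g
gravity offset the x/z/amag channels would almost never cross zero); exact
zeros after centering adopt the sign of the previous non-zero sample.
``kur``/``skw`` use population moments (n) on top of the (n−1) ``sd``;
degenerate constant windows return 0 for both, and 0 for ``cf``, so the
feature table stays rectangular.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .windows import CHANNELS, WindowSet

logger = logging.getLogger(__name__)

STATS = ("avg", "sd", "zc", "p2p", "rms", "kur", "skw", "cf", "Vrms")

#: The 36 feature-column names, channel-major: x.avg … amag.Vrms.
FEATURE_NAMES = tuple(f"{ch}.{st}" for ch in CHANNELS for st in STATS)


def avg(w) -> float:
    return float(np.mean(w))


def sd(w) -> float:
    """Sample standard deviation (n−1 denominator)."""
    return float(np.std(w, ddof=1))


def p2p(w) -> float:
    return float(np.max(w) - np.min(w))


def rms(w) -> float:
    return float(np.sqrt(np.mean(np.square(w))))


def zero_crossings(w) -> int:
    """Sign changes of the mean-centered signal.

    Samples landing exactly on zero after centering take the sign of the
    previous non-zero sample (equivalently: zeros are dropped before
    counting adjacent sign flips), so a touch of zero is not a crossing.
    """
    centered = np.asarray(w, float) - np.mean(w)
    signs = np.sign(centered)
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0
    return int(np.sum(signs[1:] * signs[:-1] < 0))


def _central_moments(w) -> tuple[float, float, float]:
    c = np.asarray(w, float) - np.mean(w)
    return float(np.mean(c**2)), float(np.mean(c**3)), float(np.mean(c**4))


def skewness(w) -> float:
    """Moment skewness m3 / m2^1.5; 0 for constant windows."""
    m2, m3, _ = _central_moments(w)
    if m2 == 0:
        logger.debug("degenerate (constant) window: skewness set to 0")
        return 0.0
    return m3 / m2**1.5


def kurtosis(w) -> float:
    """Excess kurtosis m4 / m2² − 3; 0 for constant windows."""
    m2, _, m4 = _central_moments(w)
    if m2 == 0:
        logger.debug("degenerate (constant) window: kurtosis set to 0")
        return 0.0
    return m4 / m2**2 - 3.0


def crest_factor(w) -> float:
    """max|w| / rms; 0 for the all-zero window."""
    r = rms(w)
    if r == 0:
        logger.debug("degenerate (all-zero) window: crest factor set to 0")
        return 0.0
    return float(np.max(np.abs(w))) / r


def vrms(w) -> float:
    """RMS of the running sum of the raw signal (zero initial condition)."""
    return rms(np.cumsum(w))


def extract(windows: WindowSet) -> pd.DataFrame:
    """Compute the 36-variable feature table for a window set.

    One row per window; never drops a row (degenerate windows produce the
    conventions above).  Labels and source positions are carried through in
    the ``label``/``start_index`` columns, with the label also exposed
    under its mode name (``posture`` or ``behavior``).
    """
    v = windows.values  # (n, L, 4)
    n = v.shape[0]
    cols: dict[str, np.ndarray] = {}
    for ci, ch in enumerate(CHANNELS):
        w = v[:, :, ci]  # (n, L)
        if n == 0:
            for st in STATS:
                cols[f"{ch}.{st}"] = np.empty(0)
            continue
        mean = w.mean(axis=1)
        centered = w - mean[:, None]
        m2 = (centered**2).mean(axis=1)
        m3 = (centered**3).mean(axis=1)
        m4 = (centered**4).mean(axis=1)
        rms_v = np.sqrt((w**2).mean(axis=1))
        ok = m2 > 0
        if not ok.all():
            logger.info("%d degenerate window(s) on channel %s", int((~ok).sum()), ch)

        cols[f"{ch}.avg"] = mean
        cols[f"{ch}.sd"] = w.std(axis=1, ddof=1)
        cols[f"{ch}.zc"] = _zc_rows(centered)
        cols[f"{ch}.p2p"] = w.max(axis=1) - w.min(axis=1)
        cols[f"{ch}.rms"] = rms_v
        cols[f"{ch}.kur"] = np.where(ok, m4 / np.where(ok, m2, 1) ** 2 - 3.0, 0.0)
        cols[f"{ch}.skw"] = np.where(ok, m3 / np.where(ok, m2, 1) ** 1.5, 0.0)
        cols[f"{ch}.cf"] = np.where(rms_v > 0, np.abs(w).max(axis=1) / np.where(rms_v > 0, rms_v, 1), 0.0)
        cols[f"{ch}.Vrms"] = np.sqrt((np.cumsum(w, axis=1) ** 2).mean(axis=1))

    table = pd.DataFrame(cols, columns=list(FEATURE_NAMES))
    table[windows.mode] = windows.labels
    table["start_index"] = windows.start_indices
    return table


def _zc_rows(centered: np.ndarray) -> np.ndarray:
    """Row-wise zero-crossing counts of already-centered windows."""
    signs = np.sign(centered)
    out = np.empty(len(centered), int)
    for i, row in enumerate(signs):
        nz = row[row != 0]
        out[i] = int(np.sum(nz[1:] * nz[:-1] < 0)) if nz.size > 1 else 0
    return out
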