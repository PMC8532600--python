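"""Synthetic 5 Hz triaxial accelerometer traces with known labels.

The study's recordings are not publicly deposited, so downstream stages are
exercised on simulated signals that reproduce the statistical structure the
analysis relies on:

* a **static gravity component** whose direction in the sensor frame is set
  by the posture — with the sensor on the left flank, standing puts gravity
  along −x (the vertical axis), left sternal recumbency presses the sensor
  toward the ground (−z dominant) and right sternal recumbency rolls it
  skyward (+z dominant);
* **behavior-dependent dynamics** superimposed on gravity — quasi-periodic
  jaw-cycle oscillations for rumination and feeding, sparse step impulses
  for locomotion, and near-quiescence for resting and standing still;
* white measurement noise.

Bout transitions are smoothed over ~1.5 s and flagged ambiguous, mimicking
the removal of observations the observers could not assign univocally.
All randomness is driven by explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    AMBIGUOUS,
    BEHAVIORS,
    POSTURES,
    SAMPLE_PERIOD_S,
    SAMPLE_RATE_HZ,
    AnnotationInterval,
)

#: Ethogram consistency: which postures each behavior may occur in.
#: Resting is by definition recumbent; feeding, moving and standing still
#: require standing; rumination happens both standing and lying.
ALLOWED_POSTURES = {
    "feeding": ("S",),
    "moving": ("S",),
    "standing_still": ("S",),
    "resting": ("RSR", "LSR"),
    "ruminating": ("S", "RSR", "LSR"),
}

_DEFAULT_EPOCH = np.datetime64("2019-04-01T11:00:00")


@dataclass(frozen=True)
class PostureModel:
    """Static orientation model for one posture.

    ``gravity_unit_vector`` is the direction of gravity in the sensor frame
    (units of g, unit norm); ``orientation_jitter_deg`` is the SD of a small
    random per-bout tilt, emulating animal-to-bout variation in how the
    flank sits relative to the ground.
    """

    posture: str
    gravity_unit_vector: tuple[float, float, float]
    orientation_jitter_deg: float = 5.0

    def __post_init__(self) -> None:
        g = np.asarray(self.gravity_unit_vector, float)
        if not np.isclose(np.linalg.norm(g), 1.0, atol=1e-8):
            raise ValueError("gravity_unit_vector must have unit norm")
        if self.orientation_jitter_deg < 0:
            raise ValueError("orientation_jitter_deg must be >= 0")


@dataclass(frozen=True)
class BehaviorModel:
    """Dynamic-signal model for one behavior.

    amplitude_g
        Scale of the deterministic dynamic component (g).
    dominant_freq_hz
        Frequency of a sinusoidal component (0 = none); must sit below the
        2.5 Hz Nyquist limit of the 5 Hz logger.
    burst_rate_hz
        Rate of Poisson-timed impulse events (0 = none), e.g. steps.
    noise_sd_g
        White-noise SD per axis (g); zero gives the noise-free limit used
        in analytic checks.
    """

    behavior: str
    amplitude_g: float
    dominant_freq_hz: float = 0.0
    burst_rate_hz: float = 0.0
    noise_sd_g: float = 0.01

    def __post_init__(self) -> None:
        if self.amplitude_g < 0:
            raise ValueError("amplitude_g must be >= 0")
        if not 0 <= self.dominant_freq_hz < SAMPLE_RATE_HZ / 2:
            raise ValueError("dominant_freq_hz must lie in [0, Nyquist)")
        if self.noise_sd_g < 0:
            raise ValueError("noise_sd_g must be >= 0")


def _unit(v: tuple[float, float, float]) -> tuple[float, float, float]:
    a = np.asarray(v, float)
    return tuple(a / np.linalg.norm(a))


#: Default posture conventions (sensor on the left flank): recumbency rolls
#: the flank toward (LSR) or away from (RSR) the ground with a slight
#: residual pitch.
DEFAULT_POSTURES: dict[str, PostureModel] = {
    "S": PostureModel("S", (-1.0, 0.0, 0.0)),
    "LSR": PostureModel("LSR", _unit((-0.2, 0.0, -0.98))),
    "RSR": PostureModel("RSR", _unit((-0.2, 0.0, 0.98))),
}

#: Default behavior dynamics.  Values are simulator choices calibrated to be
#: physically plausible, not measurements: rumination is a regular ~1 Hz jaw
#: cycle of small amplitude, feeding a rougher ~0.8 Hz cycle with tearing
#: bursts, moving sparse 0.3 g step impulses (at least a step every 10 s),
#: resting and standing still essentially quiescent.
DEFAULT_BEHAVIORS: dict[str, BehaviorModel] = {
    "resting": BehaviorModel("resting", amplitude_g=0.01, noise_sd_g=0.01),
    "ruminating": BehaviorModel("ruminating", amplitude_g=0.05, dominant_freq_hz=1.0, noise_sd_g=0.015),
    "feeding": BehaviorModel("feeding", amplitude_g=0.15, dominant_freq_hz=0.8, burst_rate_hz=0.3, noise_sd_g=0.03),
    "standing_still": BehaviorModel("standing_still", amplitude_g=0.0, noise_sd_g=0.02),
    "moving": BehaviorModel("moving", amplitude_g=0.3, burst_rate_hz=0.5, noise_sd_g=0.04),
}

#: Session time-budget shares (posture, behavior) -> fraction of time, shaped
#: like the late-morning observation mixture of the study design: ~60%
#: standing / ~40% lying, resting the single largest behavior.
DEFAULT_MIXTURE: dict[tuple[str, str], float] = {
    ("S", "feeding"): 0.184,
    ("S", "moving"): 0.185,
    ("S", "standing_still"): 0.204,
    ("S", "ruminating"): 0.025,
    ("RSR", "ruminating"): 0.058,
    ("LSR", "ruminating"): 0.035,
    ("RSR", "resting"): 0.195,
    ("LSR", "resting"): 0.114,
}


@dataclass(frozen=True)
class Bout:
    posture: str
    behavior: str
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("bout duration must be > 0")
        _check_pair(self.posture, self.behavior)


@dataclass
class SessionSchedule:
    """Ordered bout plan for one simulated observation session."""

    bouts: list[Bout]
    ambiguous_fraction: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ambiguous_fraction < 1:
            raise ValueError("ambiguous_fraction must lie in [0, 1)")

    @property
    def total_duration_s(self) -> float:
        return sum(b.duration_s for b in self.bouts)

    def share_of(self, mode: str, label: str) -> float:
        """Fraction of scheduled time carrying ``label`` in ``mode``."""
        tot = self.total_duration_s
        return sum(b.duration_s for b in self.bouts if getattr(b, mode) == label) / tot


def _check_pair(posture: str, behavior: str) -> None:
    if posture not in POSTURES:
        raise ValueError(f"unknown posture {posture!r}")
    if behavior not in BEHAVIORS:
        raise ValueError(f"unknown behavior {behavior!r}")
    if posture not in ALLOWED_POSTURES[behavior]:
        raise ValueError(f"ethogram-inconsistent pair: {behavior!r} cannot occur in posture {posture!r}")


def _jittered_gravity(model: PostureModel, rng: np.random.Generator) -> np.ndarray:
    """Gravity direction tilted by a small random per-bout rotation."""
    g = np.asarray(model.gravity_unit_vector, float)
    if model.orientation_jitter_deg == 0:
        return g
    tilt = np.deg2rad(model.orientation_jitter_deg) * rng.standard_normal(3)
    # small-angle rotation: add a perpendicular perturbation, renormalize
    perturbed = g + np.cross(tilt, g)
    return perturbed / np.linalg.norm(perturbed)


def _burst_train(n: int, rate_hz: float, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson-timed impulses with a short exponential-decay tail (one axis)."""
    out = np.zeros(n)
    if rate_hz <= 0 or amplitude <= 0:
        return out
    events = rng.random(n) < rate_hz * SAMPLE_PERIOD_S
    out[events] = amplitude * rng.choice([-1.0, 1.0], events.sum()) * (1 + 0.5 * rng.random(events.sum()))
    # ~0.4 s decay tail at 5 Hz
    kernel = np.exp(-np.arange(4) / 2.0)
    return np.convolve(out, kernel)[:n]


def simulate_bout(
    posture: PostureModel | str,
    behavior: BehaviorModel | str,
    duration_s: float,
    seed: int,
    start_time: np.datetime64 = _DEFAULT_EPOCH,
) -> pd.DataFrame:
    """Simulate one constant-label bout.

    The trace is ``round(duration_s * 5)`` samples of

    ``gravity (tilted per bout) + sinusoid + impulse bursts + white noise``

    labeled with the bout's posture and behavior.  Deterministic given
    ``seed``.  Raises for ethogram-inconsistent (posture, behavior) pairs.
    """
    pm = DEFAULT_POSTURES[posture] if isinstance(posture, str) else posture
    bm = DEFAULT_BEHAVIORS[behavior] if isinstance(behavior, str) else behavior
    _check_pair(pm.posture, bm.behavior)
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")

    n = int(round(duration_s * SAMPLE_RATE_HZ))
    rng = np.random.default_rng(seed)
    t = np.arange(n) * SAMPLE_PERIOD_S

    signal = np.tile(_jittered_gravity(pm, rng), (n, 1))

    if bm.dominant_freq_hz > 0 and bm.amplitude_g > 0:
        # oscillation couples mostly into the fore-aft (y) axis with some
        # leakage into z: jaw/head cycles rock the flank, not lift it
        direction = np.array([0.15, 1.0, 0.35]) + 0.1 * rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        phase = rng.uniform(0, 2 * np.pi)
        osc = bm.amplitude_g * np.sin(2 * np.pi * bm.dominant_freq_hz * t + phase)
        signal += osc[:, None] * direction

    if bm.burst_rate_hz > 0:
        for axis in range(3):
            signal[:, axis] += _burst_train(n, bm.burst_rate_hz, bm.amplitude_g, rng)
    elif bm.dominant_freq_hz == 0 and bm.amplitude_g > 0:
        # unstructured low-amplitude body motion (e.g. resting micro-movements)
        signal += bm.amplitude_g * rng.standard_normal((n, 3))

    signal += bm.noise_sd_g * rng.standard_normal((n, 3))

    times = start_time + (np.arange(n) * int(SAMPLE_PERIOD_S * 1000)).astype("timedelta64[ms]")
    return pd.DataFrame(
        {
            "time": times,
            "x": signal[:, 0],
            "y": signal[:, 1],
            "z": signal[:, 2],
            "posture": pm.posture,
            "behavior": bm.behavior,
        }
    )


def simulate_session(
    schedule: SessionSchedule,
    posture_models: dict[str, PostureModel] | None = None,
    behavior_models: dict[str, BehaviorModel] | None = None,
    start_time: np.datetime64 = _DEFAULT_EPOCH,
) -> tuple[pd.DataFrame, list[AnnotationInterval]]:
    """Simulate a full observation session from a bout schedule.

    Returns the concatenated labeled trace and the matching ground-truth
    annotation intervals (including the ambiguous transition intervals), so
    that ``apply_annotations`` on the intervals reproduces the trace labels.

    Orientation changes at posture transitions are smoothed over ~1.5 s;
    a band of samples around every bout boundary, sized so that the session
    carries ``schedule.ambiguous_fraction`` ambiguous samples overall, is
    flagged ambiguous in both label channels.
    """
    if not schedule.bouts:
        raise ValueError("schedule has no bouts")
    pms = posture_models or DEFAULT_POSTURES
    bms = behavior_models or DEFAULT_BEHAVIORS

    seeds = np.random.SeedSequence(schedule.seed).generate_state(len(schedule.bouts))
    pieces = []
    t0 = start_time
    for bout, s in zip(schedule.bouts, seeds):
        piece = simulate_bout(pms[bout.posture], bms[bout.behavior], bout.duration_s, int(s) % (2**31), t0)
        pieces.append(piece)
        t0 = piece["time"].iloc[-1].to_datetime64() + np.timedelta64(int(SAMPLE_PERIOD_S * 1000), "ms")
    trace = pd.concat(pieces, ignore_index=True)

    # smooth posture flips: short moving average across each boundary
    boundaries = np.cumsum([len(p) for p in pieces])[:-1]
    half = int(round(0.75 * SAMPLE_RATE_HZ))  # ~1.5 s total
    xyz = trace[["x", "y", "z"]].to_numpy()
    for b, (prev, nxt) in zip(boundaries, zip(schedule.bouts, schedule.bouts[1:])):
        if prev.posture == nxt.posture:
            continue
        lo, hi = max(0, b - half), min(len(trace), b + half)
        seg = xyz[max(0, lo - 2) : min(len(trace), hi + 2)]
        sm = pd.DataFrame(seg).rolling(5, center=True, min_periods=1).mean().to_numpy()
        xyz[lo:hi] = sm[lo - max(0, lo - 2) : lo - max(0, lo - 2) + (hi - lo)]
    trace[["x", "y", "z"]] = xyz

    # ambiguous band at each boundary, sized to hit the target overall share
    if boundaries.size and schedule.ambiguous_fraction > 0:
        per_boundary = int(round(schedule.ambiguous_fraction * len(trace) / boundaries.size))
        half_band = max(1, per_boundary // 2)
        amb = np.zeros(len(trace), bool)
        for b in boundaries:
            amb[max(0, b - half_band) : min(len(trace), b + half_band)] = True
        trace.loc[amb, ["posture", "behavior"]] = AMBIGUOUS

    intervals = _intervals_from_labels(trace)
    return trace, intervals


def _intervals_from_labels(trace: pd.DataFrame) -> list[AnnotationInterval]:
    """Ground-truth intervals matching the trace's label runs."""
    lab = trace["posture"].astype(str) + "\x00" + trace["behavior"].astype(str)
    change = np.flatnonzero(lab.to_numpy()[1:] != lab.to_numpy()[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(trace)]])
    step = pd.Timedelta(seconds=SAMPLE_PERIOD_S)
    out = []
    times = pd.DatetimeIndex(trace["time"])
    for s, e in zip(starts, ends):
        out.append(
            AnnotationInterval(
                start=times[s],
                end=times[e - 1] + step,
                posture=trace["posture"].iloc[s],
                behavior=trace["behavior"].iloc[s],
            )
        )
    return out


def default_schedule(
    duration_s: float = 5400.0,
    seed: int = 0,
    mixture: dict[tuple[str, str], float] | None = None,
    mean_bout_s: float = 60.0,
    ambiguous_fraction: float = 0.07,
) -> SessionSchedule:
    """Build a shuffled bout schedule matching a session time budget.

    Each (posture, behavior) pair's share of ``duration_s`` follows
    ``mixture`` (default :data:`DEFAULT_MIXTURE`); pair time is split into
    bouts of roughly ``mean_bout_s`` and the bout order is shuffled.  Bout
    durations are whole numbers of 5 Hz samples and sum exactly to
    ``round(duration_s * 5)`` samples, so a simulated session of the
    schedule has a predictable length.
    """
    mix = mixture or DEFAULT_MIXTURE
    rng = np.random.default_rng(seed)
    total_samples = int(round(duration_s * SAMPLE_RATE_HZ))

    # largest-remainder allocation of samples across pairs
    shares = np.array(list(mix.values()), float)
    shares /= shares.sum()
    ideal = shares * total_samples
    alloc = np.floor(ideal).astype(int)
    remainder = total_samples - alloc.sum()
    alloc[np.argsort(ideal - np.floor(ideal))[::-1][:remainder]] += 1

    bouts: list[Bout] = []
    mean_bout_samples = mean_bout_s * SAMPLE_RATE_HZ
    for (posture, behavior), n_pair in zip(mix.keys(), alloc):
        if n_pair == 0:
            continue
        k = max(1, int(round(n_pair / mean_bout_samples)))
        # jitter bout lengths +-30% around the even split, preserve the total
        w = 1 + 0.3 * (2 * rng.random(k) - 1)
        counts = np.floor(w / w.sum() * n_pair).astype(int)
        counts[counts == 0] = 1
        counts[0] += n_pair - counts.sum()
        for c in counts:
            bouts.append(Bout(posture, behavior, float(c) / SAMPLE_RATE_HZ))
    order = rng.permutation(len(bouts))
    return SessionSchedule([bouts[i] for i in order], ambiguous_fraction=ambiguous_fraction, seed=seed)
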