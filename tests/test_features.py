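"""Window statistics against brute-force oracles and their invariances."""

import math

import numpy as np
import pandas as pd
import pytest

from flanksense import features, io, simulate, windows

# ---------------------------------------------------------------------------
# independent loop-based oracles


def oracle_avg(w):
    return sum(w) / len(w)


def oracle_sd(w):
    m = oracle_avg(w)
    return math.sqrt(sum((v - m) ** 2 for v in w) / (len(w) - 1))


def oracle_p2p(w):
    return max(w) - min(w)


def oracle_rms(w):
    return math.sqrt(sum(v * v for v in w) / len(w))


def oracle_zc(w):
    m = oracle_avg(w)
    last = 0.0
    count = 0
    for v in w:
        s = 1 if v - m > 0 else (-1 if v - m < 0 else 0)
        if s == 0:
            continue
        if last != 0 and s != last:
            count += 1
        last = s
    return count


def oracle_skw(w):
    m = oracle_avg(w)
    m2 = sum((v - m) ** 2 for v in w) / len(w)
    m3 = sum((v - m) ** 3 for v in w) / len(w)
    return 0.0 if m2 == 0 else m3 / m2**1.5


def oracle_kur(w):
    m = oracle_avg(w)
    m2 = sum((v - m) ** 2 for v in w) / len(w)
    m4 = sum((v - m) ** 4 for v in w) / len(w)
    return 0.0 if m2 == 0 else m4 / m2**2 - 3.0


def oracle_cf(w):
    r = oracle_rms(w)
    return 0.0 if r == 0 else max(abs(v) for v in w) / r


def oracle_vrms(w):
    total = 0.0
    run = 0.0
    for v in w:
        run += v
        total += run * run
    return math.sqrt(total / len(w))


ORACLES = {
    "avg": (features.avg, oracle_avg),
    "sd": (features.sd, oracle_sd),
    "p2p": (features.p2p, oracle_p2p),
    "rms": (features.rms, oracle_rms),
    "zc": (features.zero_crossings, oracle_zc),
    "skw": (features.skewness, oracle_skw),
    "kur": (features.kurtosis, oracle_kur),
    "cf": (features.crest_factor, oracle_cf),
    "Vrms": (features.vrms, oracle_vrms),
}


@pytest.mark.parametrize("name", list(ORACLES))
def test_operator_matches_loop_oracle(name, rng):
    fn, oracle = ORACLES[name]
    for _ in range(20):
        w = rng.normal(scale=rng.uniform(0.01, 2.0), size=40) + rng.uniform(-1, 1)
        assert fn(w) == pytest.approx(oracle(list(w)), abs=1e-12, rel=1e-12)


class TestClosedForms:
    def test_constant_window(self):
        w = np.full(40, -2.5)
        assert features.avg(w) == -2.5
        assert features.sd(w) == 0.0
        assert features.p2p(w) == 0.0
        assert features.rms(w) == 2.5
        assert features.zero_crossings(w) == 0
        assert features.crest_factor(w) == 1.0
        # degenerate convention: flat windows report 0 moments
        assert features.skewness(w) == 0.0 and features.kurtosis(w) == 0.0

    def test_alternating_signs(self):
        w = np.tile([-1.0, 1.0], 20)
        assert features.avg(w) == 0.0
        assert features.p2p(w) == 2.0
        assert features.rms(w) == 1.0
        assert features.crest_factor(w) == 1.0
        assert features.zero_crossings(w) == 39  # maximal
        assert features.kurtosis(w) == pytest.approx(-2.0, abs=1e-12)

    def test_symmetric_window_has_zero_skewness(self, rng):
        half = rng.normal(size=20)
        w = np.concatenate([half, -half])
        assert features.skewness(w) == pytest.approx(0.0, abs=1e-12)

    def test_full_cycle_sine_crest_factor(self):
        w = np.sin(2 * np.pi * np.arange(40) / 40)
        assert features.crest_factor(w) == pytest.approx(np.sqrt(2), abs=1e-3)

    def test_vrms_step_integral(self):
        assert features.vrms(np.zeros(40)) == 0.0
        w = np.zeros(40)
        w[0] = 1.0  # running sum is the unit step
        assert features.vrms(w) == pytest.approx(1.0, abs=1e-12)

    def test_zero_touch_is_not_a_crossing(self):
        # zero-mean window with exact zeros after centering: +,0,+ does not
        # count, the zeros adopt the previous non-zero sign
        w = [1.0, 0.0, 1.0, -1.0, 0.0, -1.0]
        assert features.zero_crossings(w) == 1
        # +,0,- is a single crossing, not two
        assert features.zero_crossings([1.0, 0.0, -1.0]) == 1


class TestInvariances:
    def test_rms_identity(self, rng):
        """rms^2 = avg^2 + population variance, every window."""
        for _ in range(30):
            w = rng.normal(loc=rng.uniform(-2, 2), size=40)
            m2 = np.mean((w - w.mean()) ** 2)
            assert features.rms(w) ** 2 == pytest.approx(features.avg(w) ** 2 + m2, abs=1e-10)

    def test_affine_invariance_of_shape_statistics(self, rng):
        w = rng.normal(size=40)
        a, b = 3.7, -1.2
        assert features.skewness(a * w + b) == pytest.approx(features.skewness(w), abs=1e-9)
        assert features.kurtosis(a * w + b) == pytest.approx(features.kurtosis(w), abs=1e-9)

    def test_scale_invariance_of_zc_and_cf(self, rng):
        w = rng.normal(loc=0.5, size=40)
        assert features.zero_crossings(5.0 * w) == features.zero_crossings(w)
        assert features.crest_factor(5.0 * w) == pytest.approx(features.crest_factor(w), abs=1e-12)


class TestExtract:
    def test_schema_and_gravity_limit(self):
        pm = simulate.PostureModel("S", (-1.0, 0.0, 0.0), orientation_jitter_deg=0.0)
        bm = simulate.BehaviorModel("standing_still", amplitude_g=0.0, noise_sd_g=0.001)
        tr = simulate.simulate_bout(pm, bm, duration_s=8.0, seed=1)
        ws, _ = windows.segment(tr, "posture")
        table = features.extract(ws)
        assert list(table.columns[:36]) == list(features.FEATURE_NAMES)
        row = table.iloc[0]
        assert row["x.avg"] == pytest.approx(-1.0, abs=0.01)
        assert row["y.avg"] == pytest.approx(0.0, abs=0.01)
        assert row["z.avg"] == pytest.approx(0.0, abs=0.01)
        assert row["amag.avg"] == pytest.approx(1.0, abs=0.01)
        assert row["posture"] == "S"

    def test_empty_window_list(self):
        ws, _ = windows.segment(
            pd.DataFrame({"time": [], "x": [], "y": [], "z": [], "posture": [], "behavior": []}),
            "posture",
        )
        table = features.extract(ws)
        assert table.empty
        assert list(table.columns[:36]) == list(features.FEATURE_NAMES)

    def test_vectorized_extract_matches_scalar_operators(self, default_session, rng):
        """Row/column spot checks of the fast path against the scalar API."""
        _, trace, _ = default_session
        kept, _ = io.drop_ambiguous(trace, "posture")
        ws, _ = windows.segment(kept, "posture")
        table = features.extract(ws)
        assert not table[list(features.FEATURE_NAMES)].isna().any().any()
        picks = rng.integers(0, len(ws), size=5)
        for i in picks:
            for ci, ch in enumerate(windows.CHANNELS):
                w = ws.values[i, :, ci]
                for st, (fn, _) in ORACLES.items():
                    assert table.iloc[int(i)][f"{ch}.{st}"] == pytest.approx(fn(w), abs=1e-10), (ch, st)
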