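"""End-to-end orchestration: simulate/load → window → featurize → prune →
split → fit → evaluate, with one global seed feeding per-stage substreams
and every artifact persisted to a run directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features, io, metrics, modeling, simulate, windows

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``sensor_csv``/``annotations_csv`` point at recorded data, or
    (default) a synthetic session of ``duration_s`` seconds is simulated.
    """

    mode: str = "posture"
    sensor_csv: str | None = None
    annotations_csv: str | None = None
    duration_s: float = 7200.0
    ambiguous_fraction: float = 0.07
    window_len: int = windows.WINDOW_LEN
    stride: int = windows.STRIDE
    cutoff: float = 0.8
    train_fraction: float = 0.75
    algorithms: tuple[str, ...] = modeling.ALGORITHMS
    seed: int = 0
    outdir: str = "runs/run0"

    def __post_init__(self) -> None:
        if self.mode not in ("posture", "behavior"):
            raise ValueError(f"mode must be 'posture' or 'behavior', got {self.mode!r}")
        unknown = set(self.algorithms) - set(modeling.ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithm(s) {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        if "algorithms" in cfg:
            cfg["algorithms"] = tuple(cfg["algorithms"])
        return cls(**cfg)


@dataclass
class RunResult:
    config: RunConfig
    feature_table: pd.DataFrame
    prune: modeling.PruneResult
    predictions: pd.DataFrame
    confusions: dict[str, metrics.ConfusionMatrix]
    overall: pd.DataFrame
    by_class: pd.DataFrame
    counts: dict[str, int] = field(default_factory=dict)


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def build_feature_table(config: RunConfig) -> tuple[pd.DataFrame, dict[str, int]]:
    """Stages up to the tidy feature table, with bookkeeping counts."""
    sim_seed = _seeds(config.seed, 1)[0]
    if config.sensor_csv:
        trace = io.read_sensor_csv(config.sensor_csv)
        if config.annotations_csv is None:
            raise ValueError("annotations_csv required with sensor_csv")
        trace = io.apply_annotations(trace, io.read_annotations(config.annotations_csv))
    else:
        schedule = simulate.default_schedule(
            config.duration_s, seed=sim_seed, ambiguous_fraction=config.ambiguous_fraction
        )
        trace, _ = simulate.simulate_session(schedule)

    kept, removal = io.drop_ambiguous(trace, config.mode)
    ws, seg = windows.segment(kept, config.mode, config.window_len, config.stride)
    table = features.extract(ws)
    counts = {
        "samples_total": removal.total,
        "samples_removed": removal.removed,
        "samples_used": removal.retained,
        "windows_candidate": seg.candidates,
        "windows_retained": seg.retained,
        "windows_excluded": seg.excluded,
    }
    logger.info("bookkeeping: %s", counts)
    return table, counts


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline and persist artifacts under ``outdir``.

    Deterministic given ``config.seed``: the simulator, the split and every
    seeded classifier draw their seeds from one seed sequence.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seeds(config.seed, 3 + len(config.algorithms))

    table, counts = build_feature_table(config)
    if table.empty:
        raise RuntimeError("pipeline produced no windows; lengthen the session")
    table.to_csv(out / "features.csv", index=False)

    prune = modeling.prune_correlated(table, cutoff=config.cutoff)
    (out / "prune.json").write_text(
        json.dumps({"removed": prune.removed, "retained": prune.retained}, indent=2)
    )

    split = modeling.SplitSpec(train_fraction=config.train_fraction, seed=seeds[1])
    train, test, norm = modeling.split_and_normalize(table, split, prune.retained)
    counts["rows_train"], counts["rows_test"] = len(train), len(test)

    preds = pd.DataFrame({"row": np.arange(len(test)), "actual": test[config.mode]})
    classes = io.POSTURES if config.mode == "posture" else io.BEHAVIORS
    observed = tuple(c for c in classes if c in set(table[config.mode]))
    confusions: dict[str, metrics.ConfusionMatrix] = {}
    overall_rows, class_frames = [], []
    for alg, s in zip(config.algorithms, seeds[3:]):
        spec = modeling.ModelSpec(alg, seed=s)
        yhat = modeling.fit_predict(spec, train, test, prune.retained, config.mode)
        preds[f"predicted_{alg}"] = yhat
        cm = metrics.build_confusion(preds["actual"], yhat, observed)
        confusions[alg] = cm
        om = metrics.overall_metrics(cm)
        overall_rows.append({"model": alg, **dataclasses.asdict(om)})
        panel = metrics.class_metrics(cm).reset_index(names="class")
        panel.insert(0, "model", alg)
        class_frames.append(panel)
        cm.to_frame().to_csv(out / f"confusion_{alg}.csv")

    overall = pd.DataFrame(overall_rows).set_index("model")
    by_class = pd.concat(class_frames, ignore_index=True)
    preds.to_csv(out / "predictions.csv", index=False)
    overall.to_csv(out / "overall_metrics.csv")
    by_class.to_csv(out / "class_metrics.csv", index=False)
    (out / "counts.json").write_text(json.dumps(counts, indent=2))
    cfg_dict = dataclasses.asdict(config)
    cfg_dict["algorithms"] = list(cfg_dict["algorithms"])
    (out / "config.yaml").write_text(yaml.safe_dump(cfg_dict))

    return RunResult(config, table, prune, preds, confusions, overall, by_class, counts)
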