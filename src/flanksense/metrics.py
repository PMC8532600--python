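"""Confusion matrices and the multi-class assessment panel.

A confusion matrix here is laid out **predicted in rows, actual in
columns**.  From it the module derives:

* overall metrics — accuracy, Cohen's kappa, an exact (Clopper–Pearson)
  95% confidence interval for the accuracy, the no-information rate (NIR,
  the accuracy of always predicting the most prevalent actual class) and a
  one-sided exact binomial p-value for accuracy > NIR;
* per-class one-vs-rest metrics — sensitivity, specificity, precision
  (PPV), NPV, prevalence and balanced accuracy.

The published confusion matrices for the four classifiers on the posture
and behavior test sets ship as package fixtures, together with the
published metric panels, so :func:`reproduce_tables` can re-derive every
printed metric from the printed counts and flag any disagreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

__all__ = [
    "ConfusionMatrix",
    "OverallMetrics",
    "build_confusion",
    "overall_metrics",
    "class_metrics",
    "load_reference_confusions",
    "load_reference_overall",
    "load_reference_by_class",
    "reproduce_tables",
    "matches_printed",
]


@dataclass
class ConfusionMatrix:
    """K-class confusion counts, rows = predicted, columns = actual."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def predicted_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def actual_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def one_vs_rest(self, cls: str) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for one class against the rest."""
        k = self.classes.index(cls)
        tp = int(self.counts[k, k])
        fp = int(self.predicted_totals[k]) - tp
        fn = int(self.actual_totals[k]) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))

    def permuted(self, order: Sequence[str]) -> "ConfusionMatrix":
        idx = [self.classes.index(c) for c in order]
        return ConfusionMatrix(tuple(order), self.counts[np.ix_(idx, idx)])


def build_confusion(
    actual: Sequence[str], predicted: Sequence[str], classes: Sequence[str]
) -> ConfusionMatrix:
    """Tally a confusion matrix from parallel label lists.

    ``counts[i, j]`` counts rows predicted as ``classes[i]`` whose actual
    label is ``classes[j]``.
    """
    actual = np.asarray(actual, object)
    predicted = np.asarray(predicted, object)
    if len(actual) != len(predicted):
        raise ValueError(f"length mismatch: {len(actual)} actual vs {len(predicted)} predicted")
    if len(actual) == 0:
        raise ValueError("empty label lists")
    index = {c: i for i, c in enumerate(classes)}
    unknown = {l for l in set(actual) | set(predicted) if l not in index}
    if unknown:
        raise ValueError(f"labels outside the class list: {sorted(unknown)}")
    k = len(classes)
    counts = np.zeros((k, k), np.int64)
    np.add.at(counts, ([index[p] for p in predicted], [index[a] for a in actual]), 1)
    return ConfusionMatrix(tuple(classes), counts)


@dataclass
class OverallMetrics:
    accuracy: float
    kappa: float
    ci_lower: float
    ci_upper: float
    nir: float
    p_value: float


def overall_metrics(cm: ConfusionMatrix, conf_level: float = 0.95) -> OverallMetrics:
    """Accuracy, kappa, exact binomial CI, NIR and accuracy-vs-NIR p-value.

    kappa = (p_o − p_e) / (1 − p_e) with the usual marginal chance
    agreement p_e = Σ_k rowshare_k · colshare_k; if p_e = 1 (one class on
    both axes) kappa is undefined and returned as NaN.  The CI is the
    Clopper–Pearson interval for ``trace`` successes in ``total`` trials;
    the p-value is the one-sided exact binomial P(X ≥ trace | total, NIR).
    """
    n = cm.total
    trace = int(np.trace(cm.counts))
    acc = trace / n
    pe = float((cm.predicted_totals * cm.actual_totals).sum()) / n**2
    kappa = math.nan if pe == 1.0 else (acc - pe) / (1.0 - pe)
    ci = binomtest(trace, n).proportion_ci(confidence_level=conf_level, method="exact")
    nir = float(cm.actual_totals.max()) / n
    p = binomtest(trace, n, p=nir, alternative="greater").pvalue
    return OverallMetrics(acc, kappa, float(ci.low), float(ci.high), nir, float(p))


def class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest panel: sensitivity, specificity, precision, NPV,
    prevalence and balanced accuracy per class.

    Undefined ratios (zero denominator, e.g. a class never observed) are
    NaN; balanced accuracy inherits NaN from its undefined half.
    """
    rows = {}
    n = cm.total
    for cls in cm.classes:
        tp, fp, fn, tn = cm.one_vs_rest(cls)
        sens = tp / (tp + fn) if tp + fn else math.nan
        spec = tn / (tn + fp) if tn + fp else math.nan
        rows[cls] = {
            "sensitivity": sens,
            "specificity": spec,
            "precision": tp / (tp + fp) if tp + fp else math.nan,
            "npv": tn / (tn + fn) if tn + fn else math.nan,
            "prevalence": (tp + fn) / n,
            "balanced_accuracy": (sens + spec) / 2,
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[list(cm.classes)]


# ---------------------------------------------------------------------------
# packaged reference tables


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("flanksense.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, dtype=str)


def load_reference_confusions(task: str) -> dict[str, ConfusionMatrix]:
    """The published test-set confusion matrices, one per classifier."""
    if task not in ("posture", "behavior"):
        raise ValueError("task must be 'posture' or 'behavior'")
    df = _read_fixture(f"{task}_confusion.csv")
    classes = tuple(df.columns[2:])
    out = {}
    for model, grp in df.groupby("model", sort=False):
        grp = grp.set_index("predicted").loc[list(classes)]
        out[model] = ConfusionMatrix(classes, grp[list(classes)].astype(int).to_numpy())
    return out


def load_reference_overall(task: str) -> pd.DataFrame:
    """Published overall-metric panel (values as printed strings)."""
    return _read_fixture(f"{task}_overall_reference.csv").set_index("model")


def load_reference_by_class(task: str) -> pd.DataFrame:
    """Published per-class panel (values as printed strings)."""
    return _read_fixture(f"{task}_class_reference.csv").set_index(["class", "model"])


def matches_printed(computed: float, printed: str) -> bool:
    """Does a computed value agree with a printed one at printed precision?

    A printed ``<0.001`` matches any computed value below 0.001.  Otherwise
    the printed string fixes the decimal precision, and the computed value
    matches if printing it at that precision under either convention in
    common use — round-half or truncation toward zero — yields the printed
    digits.  (Published tables are not always consistent about which of the
    two they applied.)
    """
    printed = printed.strip()
    if printed.startswith("<"):
        return computed < float(printed[1:])
    target = float(printed)
    dp = len(printed.split(".")[1]) if "." in printed else 0
    ulp = 10.0**-dp
    rounded_ok = abs(computed - target) <= 0.5 * ulp + 1e-12
    truncated_ok = target - 1e-12 <= computed < target + ulp + 1e-12
    return rounded_ok or truncated_ok


_OVERALL_FIELDS = {
    "accuracy": "accuracy",
    "kappa": "kappa",
    "accuracy_lower": "ci_lower",
    "accuracy_upper": "ci_upper",
    "p_value": "p_value",
}


def reproduce_tables(tasks: Sequence[str] = ("posture", "behavior")) -> pd.DataFrame:
    """Re-derive every published metric from the published confusion counts.

    Returns one row per (task, model, class, metric) comparison with the
    computed value, the printed value and a match flag under
    :func:`matches_printed`.
    """
    rows = []
    for task in tasks:
        cms = load_reference_confusions(task)
        ref_overall = load_reference_overall(task)
        ref_class = load_reference_by_class(task)
        for model, cm in cms.items():
            om = overall_metrics(cm)
            for col, attr in _OVERALL_FIELDS.items():
                printed = ref_overall.loc[model, col]
                val = getattr(om, attr)
                rows.append((task, model, "", col, val, printed, matches_printed(val, printed)))
            panel = class_metrics(cm)
            for cls in cm.classes:
                for col in panel.columns:
                    printed = ref_class.loc[(cls, model), col]
                    val = panel.loc[cls, col]
                    rows.append((task, model, cls, col, val, printed, matches_printed(val, printed)))
    return pd.DataFrame(
        rows, columns=["task", "model", "class", "metric", "computed", "printed", "match"]
    )
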