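"""Patient-level diagnostic metrics, per-cutoff tables, and ROC/AUC.

Metric definitions are the standard ones — sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN),
accuracy = (TP+TN)/N — with every 0/0 ratio reported as 0.0 (the convention
a cutoff sweep needs at its degenerate ends, where e.g. no patient is
classified positive and PPV has an empty denominator). The ROC curve is
traced by the 11 cutoff-grid operating points with (0,0) and (1,1)
anchors; the AUC is the trapezoidal area under the per-FPR upper envelope
of those points (operating points sharing an FPR contribute zero width, so
only the best TPR at each FPR shapes the curve).
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsRow:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float


@dataclass
class RocCurve:
    points: list[tuple[float, float]]  # (FPR, TPR), sorted by FPR then TPR
    auc: float


def confusion(preds: dict[str, int], labels: dict[str, int]) -> ConfusionMatrix:
    """Cross-tabulate binary predictions against labels (identical keys)."""
    if set(preds) != set(labels):
        diff = sorted(set(preds) ^ set(labels))
        raise ValueError(f"prediction/label key mismatch: {diff}")
    tp = fp = tn = fn = 0
    for pid, pred in preds.items():
        if labels[pid] == 1:
            tp += pred
            fn += 1 - pred
        else:
            fp += pred
            tn += 1 - pred
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float:
    return num / den if den else 0.0


def metrics(cm: ConfusionMatrix) -> MetricsRow:
    """Sensitivity, specificity, PPV, NPV, accuracy; 0/0 -> 0.0."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return MetricsRow(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
    )


def roc_auc(rows: list[tuple[ConfusionMatrix, float]]) -> RocCurve:
    """ROC over cutoff-grid operating points; trapezoidal AUC.

    rows: (confusion matrix, cutoff) pairs, one per grid value. Anchors
    (0,0) and (1,1) are appended before integration.
    """
    if len(rows) < 2:
        raise ValueError("need at least 2 operating points")
    pts: list[tuple[float, float]] = []
    for cm, _cutoff in rows:
        if cm.fp + cm.tn == 0:
            raise ValueError("FPR undefined: no actual negatives")
        if cm.tp + cm.fn == 0:
            raise ValueError("TPR undefined: no actual positives")
        pts.append((cm.fp / (cm.fp + cm.tn), cm.tp / (cm.tp + cm.fn)))
    pts += [(0.0, 0.0), (1.0, 1.0)]
    pts.sort()
    # upper envelope: duplicate FPRs contribute zero width, keep best TPR
    env: dict[float, float] = {}
    for fpr, tpr in pts:
        env[fpr] = max(env.get(fpr, 0.0), tpr)
    xs = sorted(env)
    ys = [env[x] for x in xs]
    auc = float(np.trapezoid(ys, xs))
    return RocCurve(points=pts, auc=auc)


def performance_table(rows: list[tuple[float, ConfusionMatrix]]) -> pd.DataFrame:
    """Per-cutoff counts and metrics (holdout-style table)."""
    recs = []
    for cutoff, cm in rows:
        m = metrics(cm)
        recs.append(
            {
                "cutoff": cutoff,
                "tn": cm.tn, "fn": cm.fn, "fp": cm.fp, "tp": cm.tp,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "ppv": m.ppv,
                "npv": m.npv,
                "accuracy": m.accuracy,
            }
        )
    return pd.DataFrame.from_records(recs)


METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


def summarize_folds(fold_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean and min-max of each metric per cutoff across CV folds."""
    stacked = pd.concat(fold_tables, keys=range(len(fold_tables)), names=["fold"])
    out = {"cutoff": sorted(stacked["cutoff"].unique())}
    grouped = stacked.groupby("cutoff")
    for name in METRIC_NAMES:
        out[f"{name}_mean"] = grouped[name].mean().values
        out[f"{name}_min"] = grouped[name].min().values
        out[f"{name}_max"] = grouped[name].max().values
    return pd.DataFrame(out)


def _format_2dp(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: f"{v:.2f}")
    return out


def report_tables(
    cv_table: pd.DataFrame,
    holdout_table: pd.DataFrame,
    roc: RocCurve,
    rundir: str | PathLike,
) -> None:
    """Write cv_performance.csv, holdout_performance.csv, roc.csv and
    roc.png into rundir; metric values formatted to 2 decimals."""
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    _format_2dp(cv_table).to_csv(rundir / "cv_performance.csv", index=False)
    _format_2dp(holdout_table).to_csv(rundir / "holdout_performance.csv", index=False)
    roc_df = pd.DataFrame(roc.points, columns=["fpr", "tpr"])
    _format_2dp(roc_df).to_csv(rundir / "roc.csv", index=False)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    xs, ys = zip(*sorted(roc.points))
    ax.plot(xs, ys, marker="o", lw=1.5)
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=1)
    ax.set_xlabel("False positive rate (1 - specificity)")
    ax.set_ylabel("True positive rate (sensitivity)")
    ax.set_title(f"Patient-level ROC over cutoff grid (AUC = {roc.auc:.2f})")
    fig.tight_layout()
    fig.savefig(rundir / "roc.png", dpi=120)
    plt.close(fig)
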