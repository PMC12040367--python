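"""Tabular and graphical outputs: curve data as TSV, optional figures.

Everything the evaluation computes can be exported for external
plotting (ROC, precision-recall, calibration) and the operating-point
table is written one row per target PPV.  Figures (precision-recall
and calibration, mirroring the usual presentation of case-finding
models) are rendered only when matplotlib is installed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .evaluation import MetricReport, PredictionSet


def roc_points(preds: PredictionSet) -> list[tuple[float, float, float]]:
    """(threshold, false-positive rate, true-positive rate) per distinct score."""
    order = np.argsort(-preds.scores, kind="stable")
    s = preds.scores[order]
    y = preds.labels[order]
    boundary = np.nonzero(np.diff(s))[0]
    ends = np.append(boundary, s.size - 1)
    tp = np.cumsum(y)[ends]
    fp = (ends + 1) - tp
    n_pos = int(preds.labels.sum())
    n_neg = preds.n - n_pos
    return [
        (float(s[e]), float(f) / n_neg, float(t) / n_pos)
        for e, f, t in zip(ends, fp, tp)
    ]


def pr_points(preds: PredictionSet) -> list[tuple[float, float, float]]:
    """(threshold, recall, precision) per distinct score."""
    order = np.argsort(-preds.scores, kind="stable")
    s = preds.scores[order]
    y = preds.labels[order]
    boundary = np.nonzero(np.diff(s))[0]
    ends = np.append(boundary, s.size - 1)
    tp = np.cumsum(y)[ends]
    flagged = ends + 1
    n_pos = int(preds.labels.sum())
    return [
        (float(s[e]), float(t) / n_pos, float(t) / f)
        for e, t, f in zip(ends, tp, flagged)
    ]


def _write_tsv(rows: Sequence[Sequence], header: Sequence[str],
               path: str | Path) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(
            f"{v:.6g}" if isinstance(v, float) else str(v) for v in row
        ))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_roc_tsv(preds: PredictionSet, path: str | Path) -> None:
    _write_tsv(roc_points(preds), ("threshold", "fpr", "tpr"), path)


def write_pr_tsv(preds: PredictionSet, path: str | Path) -> None:
    _write_tsv(pr_points(preds), ("threshold", "recall", "precision"), path)


def write_calibration_tsv(report: MetricReport, path: str | Path) -> None:
    rows = [
        (r["bin_lower"], r["bin_upper"], r["mean_predicted"],
         r["observed_rate"], r["n"])
        for r in report.calibration
    ]
    _write_tsv(
        rows,
        ("bin_lower", "bin_upper", "mean_predicted", "observed_rate", "n"),
        path,
    )


def write_operating_points_tsv(report: MetricReport, path: str | Path) -> None:
    """One row per target PPV: thresholds, confusion counts, and the
    derived rates (with CI columns when they were bootstrapped)."""
    if not report.operating_points:
        Path(path).write_text("")
        return
    cols = list(report.operating_points[0])
    rows = [[r[c] for c in cols] for r in report.operating_points]
    _write_tsv(rows, cols, path)


def plot_precision_recall(
    named_preds: dict[str, PredictionSet], path: str | Path
) -> None:
    """Precision-recall curves for one or more models on the same axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, preds in named_preds.items():
        pts = pr_points(preds)
        ax.plot([p[1] for p in pts], [p[2] for p in pts], label=name)
    ax.set_xlabel("Sensitivity (recall)")
    ax.set_ylabel("PPV (precision)")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_calibration(
    named_reports: dict[str, MetricReport], path: str | Path
) -> None:
    """Observed vs predicted probability per bin, with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    lim = 0.0
    for name, report in named_reports.items():
        xs = [r["mean_predicted"] for r in report.calibration]
        ys = [r["observed_rate"] for r in report.calibration]
        lim = max(lim, max(xs + ys))
        ax.plot(xs, ys, marker="o", label=name)
    ax.plot([0, lim], [0, lim], linestyle=":", color="grey", label="ideal")
    ax.set_xlabel("Predicted probability")
    ax.set_ylabel("Observed probability")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
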