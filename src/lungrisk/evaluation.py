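"""The evaluation protocol for the risk models.

Discrimination (AUROC as the Mann-Whitney concordance, AUPRC as average
precision), accuracy of probabilities (Brier score), calibration tables,
PPV-anchored operating points for target PPVs 0.01-0.10, and 95%
percentile bootstrap confidence intervals (B = 1000 resamples of
patients, thresholds re-derived inside every resample so the PPV stays
fixed across iterations).  Also the outcome-stratified 60/20/20
train/tune/test split used for internal validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata


class InfeasiblePPVError(ValueError):
    """No threshold achieves the requested PPV on this prediction set."""


@dataclass
class PredictionSet:
    """Per-patient predicted probabilities with labels and centre ids."""

    scores: np.ndarray
    labels: np.ndarray
    centre_ids: np.ndarray | None = None
    patient_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have the same length")
        if self.scores.size == 0:
            raise ValueError("empty prediction set")
        if self.scores.min() < 0 or self.scores.max() > 1:
            raise ValueError("scores must be probabilities in [0, 1]")
        if self.centre_ids is not None:
            self.centre_ids = np.asarray(self.centre_ids)

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def subset(self, idx: np.ndarray) -> "PredictionSet":
        return PredictionSet(
            self.scores[idx],
            self.labels[idx],
            None if self.centre_ids is None else self.centre_ids[idx],
            None if self.patient_ids is None else self.patient_ids[idx],
        )


def concatenate(sets: Sequence[PredictionSet]) -> PredictionSet:
    """Stack prediction sets (the leave-centre-out 'stacking' step)."""
    return PredictionSet(
        np.concatenate([s.scores for s in sets]),
        np.concatenate([s.labels for s in sets]),
        np.concatenate(
            [
                s.centre_ids
                if s.centre_ids is not None
                else np.array(["?"] * s.n)
                for s in sets
            ]
        ),
        np.concatenate(
            [
                s.patient_ids
                if s.patient_ids is not None
                else np.array([""] * s.n)
                for s in sets
            ]
        ),
    )


def auroc(preds: PredictionSet) -> float:
    """Mann-Whitney concordance P(score_pos > score_neg) + P(tie)/2."""
    y = preds.labels
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes")
    ranks = rankdata(preds.scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(preds: PredictionSet) -> float:
    """Average precision with tied scores grouped (step interpolation)."""
    y = preds.labels
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("AUPRC requires at least one positive")
    order = np.argsort(-preds.scores, kind="stable")
    s = preds.scores[order]
    yy = y[order]
    # group boundaries where the score changes
    boundary = np.nonzero(np.diff(s))[0]
    ends = np.append(boundary, s.size - 1)
    tp = np.cumsum(yy)[ends]
    fp = (ends + 1) - tp
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(((recall - prev_recall) * precision).sum())


def brier(preds: PredictionSet) -> float:
    """Mean squared error of the predicted probabilities."""
    return float(np.mean((preds.scores - preds.labels) ** 2))


def calibration_curve(
    preds: PredictionSet, n_bins: int = 10, scheme: str = "quantile"
) -> list[dict]:
    """Bin predictions and compare mean predicted vs observed event rate.

    ``scheme="quantile"`` (default) uses deciles of the predicted
    probability, which keeps bins populated under heavy class imbalance;
    ``scheme="width"`` uses equal-width bins on [0, 1].  Bins partition
    all predictions; counts sum to n.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    s = preds.scores
    if scheme == "quantile":
        edges = np.unique(np.quantile(s, np.linspace(0, 1, n_bins + 1)))
        if edges.size < 2:
            edges = np.array([edges[0], edges[0] + 1e-12])
    elif scheme == "width":
        edges = np.linspace(0.0, 1.0, n_bins + 1)
    else:
        raise ValueError(f"unknown binning scheme: {scheme!r}")
    idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, edges.size - 2)
    rows = []
    for b in range(edges.size - 1):
        mask = idx == b
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        rows.append(
            {
                "bin_lower": float(edges[b]),
                "bin_upper": float(edges[b + 1]),
                "mean_predicted": float(s[mask].mean()),
                "observed_rate": float(preds.labels[mask].mean()),
                "n": cnt,
            }
        )
    assert sum(r["n"] for r in rows) == preds.n
    return rows


def threshold_for_ppv(preds: PredictionSet, target_ppv: float) -> float:
    """Lowest distinct-score cutoff whose achieved PPV >= target.

    Classification rule is ``score >= threshold -> positive``; among all
    feasible cutoffs the one flagging the most patients (maximal
    sensitivity) is returned, matching a case-finding reading of a fixed
    PPV.  Raises :class:`InfeasiblePPVError` when no cutoff qualifies.
    """
    if not 0.0 < target_ppv <= 1.0:
        raise ValueError("target_ppv must be in (0, 1]")
    y = preds.labels
    order = np.argsort(-preds.scores, kind="stable")
    s = preds.scores[order]
    yy = y[order]
    boundary = np.nonzero(np.diff(s))[0]
    ends = np.append(boundary, s.size - 1)
    tp = np.cumsum(yy)[ends]
    flagged = ends + 1
    ppv = tp / flagged
    feasible = np.nonzero(ppv >= target_ppv)[0]
    if feasible.size == 0:
        raise InfeasiblePPVError(
            f"no threshold achieves PPV >= {target_ppv:.3f}"
        )
    best = feasible[np.argmax(flagged[feasible])]
    return float(s[ends[best]])


@dataclass
class OperatingPoint:
    target_ppv: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv_achieved(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    def as_dict(self) -> dict:
        return {
            "target_ppv": self.target_ppv,
            "threshold": self.threshold,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv_achieved": self.ppv_achieved,
            "npv": self.npv,
        }


def operating_point(preds: PredictionSet, target_ppv: float) -> OperatingPoint:
    """Confusion counts at the PPV-anchored threshold."""
    thr = threshold_for_ppv(preds, target_ppv)
    flagged = preds.scores >= thr
    if not flagged.any():
        raise ValueError("degenerate threshold: no patient flagged")
    y = preds.labels
    tp = int((flagged & (y == 1)).sum())
    fp = int((flagged & (y == 0)).sum())
    fn = int((~flagged & (y == 1)).sum())
    tn = int((~flagged & (y == 0)).sum())
    return OperatingPoint(target_ppv, thr, tp, fp, tn, fn)


def bootstrap_ci_values(
    metric: Callable[[np.ndarray], float],
    values: np.ndarray,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI of a statistic of a plain sample.

    Same percentile construction as :func:`bootstrap_ci` but for
    unlabelled data (e.g. the mean of a measurement series).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    values = np.asarray(values)
    rng = np.random.default_rng(seed)
    n = values.shape[0]
    stats = [
        metric(values[rng.integers(0, n, size=n)]) for _ in range(B)
    ]
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(metric(values)), float(lower), float(upper)


def bootstrap_ci(
    metric: Callable[[PredictionSet], float],
    preds: PredictionSet,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI of a metric over patient resamples.

    Returns (point estimate on the original set, lower, upper).
    Resamples missing one of the classes — or infeasible for a
    PPV-anchored metric — are skipped and counted; more than 50%
    skipped raises.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    point = metric(preds)
    values = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, preds.n, size=preds.n)
        sub = preds.subset(idx)
        if sub.labels.min() == sub.labels.max():
            skipped += 1
            continue
        try:
            values.append(metric(sub))
        except (InfeasiblePPVError, ValueError):
            skipped += 1
    if skipped > B // 2:
        raise RuntimeError(
            f"unstable bootstrap: {skipped}/{B} resamples skipped"
        )
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(values, [alpha, 1.0 - alpha])
    return point, float(lower), float(upper)


@dataclass
class MetricReport:
    """Discrimination/calibration summary with percentile bootstrap CIs."""

    name: str
    n: int
    n_positive: int
    auroc: tuple[float, float, float]
    auprc: tuple[float, float, float]
    brier: tuple[float, float, float]
    calibration: list[dict]
    operating_points: list[dict]
    bootstrap_B: int
    seed: int
    infeasible_ppvs: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> dict:
        obj = {
            "name": self.name,
            "n": self.n,
            "n_positive": self.n_positive,
            "auroc": {"point": self.auroc[0], "ci_lower": self.auroc[1],
                      "ci_upper": self.auroc[2]},
            "auprc": {"point": self.auprc[0], "ci_lower": self.auprc[1],
                      "ci_upper": self.auprc[2]},
            "brier": {"point": self.brier[0], "ci_lower": self.brier[1],
                      "ci_upper": self.brier[2]},
            "calibration": self.calibration,
            "operating_points": self.operating_points,
            "infeasible_ppvs": self.infeasible_ppvs,
            "bootstrap_B": self.bootstrap_B,
            "seed": self.seed,
        }
        if path is not None:
            Path(path).write_text(json.dumps(obj, indent=2))
        return obj


DEFAULT_PPV_TARGETS = tuple(round(0.01 * i, 2) for i in range(1, 11))


def operating_point_table(
    preds: PredictionSet,
    targets: Sequence[float] = DEFAULT_PPV_TARGETS,
    B: int = 1000,
    seed: int = 0,
    with_ci: bool = True,
) -> tuple[list[dict], list[float]]:
    """Operating points for each target PPV, with bootstrap CIs on
    sensitivity/specificity/NPV (threshold re-derived per resample)."""
    rows: list[dict] = []
    infeasible: list[float] = []
    for t in targets:
        try:
            op = operating_point(preds, t)
        except (InfeasiblePPVError, ValueError):
            infeasible.append(t)
            continue
        row = op.as_dict()
        if with_ci:
            for fname in ("sensitivity", "specificity", "npv"):
                def metric(p: PredictionSet, t=t, fname=fname) -> float:
                    return getattr(operating_point(p, t), fname)

                _, lo, hi = bootstrap_ci(metric, preds, B=B, seed=seed)
                row[f"{fname}_ci_lower"] = lo
                row[f"{fname}_ci_upper"] = hi
        rows.append(row)
    return rows, infeasible


def build_metric_report(
    preds: PredictionSet,
    name: str = "",
    B: int = 1000,
    seed: int = 0,
    ppv_targets: Sequence[float] = DEFAULT_PPV_TARGETS,
    n_calibration_bins: int = 10,
    with_operating_cis: bool = False,
) -> MetricReport:
    """Full evaluation of one prediction set."""
    ops, infeasible = operating_point_table(
        preds, ppv_targets, B=B, seed=seed, with_ci=with_operating_cis
    )
    return MetricReport(
        name=name,
        n=preds.n,
        n_positive=int(preds.labels.sum()),
        auroc=bootstrap_ci(auroc, preds, B=B, seed=seed),
        auprc=bootstrap_ci(auprc, preds, B=B, seed=seed),
        brier=bootstrap_ci(brier, preds, B=B, seed=seed),
        calibration=calibration_curve(preds, n_bins=n_calibration_bins),
        operating_points=ops,
        bootstrap_B=B,
        seed=seed,
        infeasible_ppvs=infeasible,
    )


def stratified_split(
    labels: Sequence[int],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Outcome-stratified train/tune/test index split.

    Within each label class the counts match the fractions to +/-1;
    the three parts are disjoint and exhaustive.  Raises when any part
    would receive zero positives.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = idx[rng.permutation(idx.size)]
        c1 = int(round(fractions[0] * idx.size))
        c2 = int(round((fractions[0] + fractions[1]) * idx.size))
        parts[0].extend(idx[:c1])
        parts[1].extend(idx[c1:c2])
        parts[2].extend(idx[c2:])
    train, tune, test = (np.sort(np.array(p, dtype=int)) for p in parts)
    for part, pname in ((train, "train"), (tune, "tune"), (test, "test")):
        if y[part].sum() == 0:
            raise ValueError(
                f"too few positives to place at least one in the {pname} part"
            )
    return train, tune, test
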