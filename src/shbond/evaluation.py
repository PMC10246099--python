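"""Evaluation metrics and descriptive SHB statistics.

Precision/recall as a function of the classification threshold, the ROC
curve and its AUC, the SHB propensity P_SHB of a category, R histograms, and
the charged/neutral composition of bonds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve, roc_auc_score

from .hbond import HBClass, HydrogenBond, R_MIN, R_MAX

_LABEL_TO_INT = {"NHB": 0, "SHB": 1}


def _as_binary(labels: Sequence) -> np.ndarray:
    out = []
    for lab in labels:
        key = lab.value if isinstance(lab, HBClass) else str(lab)
        if key not in _LABEL_TO_INT:
            raise ValueError(f"label {lab!r} outside {{SHB, NHB}}")
        out.append(_LABEL_TO_INT[key])
    return np.asarray(out, dtype=int)


def precision_recall(
    probs: Sequence[float], labels: Sequence, threshold: float
) -> tuple[Optional[float], float]:
    """(precision, recall) of the SHB class at one threshold.

    Precision is the fraction of true SHBs among predicted SHBs and is
    undefined (returned as None) when nothing is predicted positive; recall
    is the fraction of SHBs recovered.
    """
    probs = np.asarray(probs, dtype=float)
    y = _as_binary(labels)
    if len(probs) != len(y):
        raise ValueError("probs and labels must have equal length")
    pred = probs >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return precision, recall


def roc_auc(probs: Sequence[float], labels: Sequence) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, recall) over all score thresholds, and the AUC.

    The AUC equals the probability that a random SHB outscores a random NHB
    (ties counted half), computed by trapezoidal integration of the curve.
    """
    probs = np.asarray(probs, dtype=float)
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, probs)
    auc = float(roc_auc_score(y, probs))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def pshb(n_shb: int, n_nhb: int) -> float:
    """SHB propensity: the fraction of a category's hydrogen bonds that are short."""
    if n_shb + n_nhb <= 0:
        raise ValueError("P_SHB undefined for an empty category")
    return n_shb / (n_shb + n_nhb)


def r_histogram(
    bonds: Sequence[HydrogenBond], bin_width: float = 0.1
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-kind normalized histograms of R over the hydrogen-bond window.

    Returns kind -> (bin_edges, masses) with masses summing to 1 per kind.
    """
    if not bonds:
        raise ValueError("no bonds to histogram")
    edges = np.arange(R_MIN, R_MAX + bin_width / 2, bin_width)
    out = {}
    for kind in sorted({b.kind.value for b in bonds}):
        rs = [b.R for b in bonds if b.kind.value == kind]
        counts, _ = np.histogram(rs, bins=edges)
        out[kind] = (edges, counts / counts.sum())
    return out


def charge_composition(
    bonds: Sequence[HydrogenBond], bin_width: float = 0.05
) -> dict[str, dict[str, int]]:
    """Counts of both_neutral / one_charged / both_charged bonds per R bin."""
    edges = np.arange(R_MIN, R_MAX + bin_width / 2, bin_width)
    out: dict[str, dict[str, int]] = {}
    for b in bonds:
        k = min(int((b.R - R_MIN) / bin_width), len(edges) - 2)
        key = f"{edges[k]:.2f}-{edges[k + 1]:.2f}"
        n_charged = int(b.donor.group_formal_charge != 0) + int(
            b.acceptor.group_formal_charge != 0
        )
        cat = ("both_neutral", "one_charged", "both_charged")[n_charged]
        out.setdefault(key, {"both_neutral": 0, "one_charged": 0, "both_charged": 0})
        out[key][cat] += 1
    return out


@dataclass
class EvaluationReport:
    """Threshold sweep, ROC/AUC and confusion counts at one threshold."""

    thresholds: list[float]
    precision: list[Optional[float]]
    recall: list[float]
    roc_points: list[tuple[float, float]]
    auc: float
    threshold_used: float
    confusion: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "auc": self.auc,
                "threshold": self.threshold_used,
                "confusion": self.confusion,
                "sweep": [
                    {"threshold": t, "precision": p, "recall": r}
                    for t, p, r in zip(self.thresholds, self.precision, self.recall)
                ],
                "roc": [{"fpr": f, "recall": r} for f, r in self.roc_points],
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        lines = ["threshold\tprecision\trecall"]
        for t, p, r in zip(self.thresholds, self.precision, self.recall):
            ptxt = "NA" if p is None else f"{p:.4f}"
            lines.append(f"{t:.6f}\t{ptxt}\t{r:.4f}")
        return "\n".join(lines) + "\n"


def evaluate(
    probs: Sequence[float], labels: Sequence, threshold: float = 0.870
) -> EvaluationReport:
    """Full evaluation: exact threshold sweep, ROC/AUC and confusion counts.

    The sweep grid is every distinct predicted probability plus 0 and 1, so
    the precision/recall curves are exact step functions.
    """
    probs = np.asarray(probs, dtype=float)
    y = _as_binary(labels)
    grid = sorted(set(probs.tolist()) | {0.0, 1.0})
    precisions, recalls = [], []
    for t in grid:
        p, r = precision_recall(probs, labels, t)
        precisions.append(p)
        recalls.append(r)
    roc_points, auc = roc_auc(probs, labels)
    pred = probs >= threshold
    confusion = {
        "TP": int(np.sum(pred & (y == 1))),
        "FP": int(np.sum(pred & (y == 0))),
        "FN": int(np.sum(~pred & (y == 1))),
        "TN": int(np.sum(~pred & (y == 0))),
    }
    return EvaluationReport(
        thresholds=grid,
        precision=precisions,
        recall=recalls,
        roc_points=roc_points,
        auc=auc,
        threshold_used=threshold,
        confusion=confusion,
    )
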