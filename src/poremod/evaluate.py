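"""Site-level detection metrics for per-position modification scores.

A score track (total variation percentage or energy distance) is evaluated
against ground-truth modified positions: AUROC via the mid-rank
Mann–Whitney formulation, AUPRC as step-wise average precision, thresholded
confusion matrices (score ≥ threshold predicts "modified"), and post-hoc
attribution of false positives to nearby true sites — error and signal
perturbations smear over the pore's k-mer footprint, so false calls cluster
around genuine modifications.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import UndefinedMetricError, ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class AttributionResult:
    """False positives split by proximity to any true modified position."""

    attributed: int
    unattributed: int
    attributed_positions: tuple
    unattributed_positions: tuple


class ScoredPositions:
    """Per-position scores with binary truth labels.

    Undefined positions (NaN score or defined=False) are excluded from every
    metric rather than imputed.
    """

    def __init__(self, positions, scores, labels, defined=None):
        positions = np.asarray(positions, dtype=int)
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        if defined is None:
            defined = ~np.isnan(scores)
        defined = np.asarray(defined, dtype=bool) & ~np.isnan(scores)
        if not set(np.unique(labels)) <= {0, 1}:
            raise ValidationError("labels must be binary")
        if not (len(positions) == len(scores) == len(labels) == len(defined)):
            raise ValidationError("positions, scores, labels must share length")
        self.df = pd.DataFrame(
            {"position": positions, "score": scores, "label": labels, "defined": defined}
        )

    @classmethod
    def from_scores(cls, scores: Mapping[int, float] | pd.Series,
                    truth_positions: Iterable[int]) -> "ScoredPositions":
        s = pd.Series(scores)
        truth = set(int(p) for p in truth_positions)
        labels = [1 if int(p) in truth else 0 for p in s.index]
        return cls(s.index.to_numpy(), s.to_numpy(), labels)

    def _defined(self) -> tuple[np.ndarray, np.ndarray]:
        d = self.df[self.df["defined"]]
        return d["score"].to_numpy(), d["label"].to_numpy()


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise UndefinedMetricError(
            "metric undefined: need at least one positive and one negative "
            "defined position"
        )


def auroc(sp: ScoredPositions) -> float:
    """Mid-rank Mann–Whitney AUROC: P(score⁺ > score⁻) + ½·P(tie)."""
    scores, labels = sp._defined()
    _check_two_classes(labels)
    ranks = rankdata(scores)  # mid-ranks under ties
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(sp: ScoredPositions) -> float:
    """Step-wise average precision over descending score thresholds.

    AP = Σ_k (R_k − R_{k−1}) · P_k over distinct thresholds, the
    non-interpolated estimator; ties are handled by thresholding at each
    distinct score value.
    """
    scores, labels = sp._defined()
    _check_two_classes(labels)
    order = np.argsort(-scores, kind="mergesort")
    scores, labels = scores[order], labels[order]
    # group ties: cumulative counts at the end of each distinct-score block
    distinct = np.nonzero(np.diff(scores))[0]
    block_ends = np.r_[distinct, len(scores) - 1]
    cum_tp = np.cumsum(labels)[block_ends]
    cum_n = block_ends + 1
    precision = cum_tp / cum_n
    n_pos = labels.sum()
    recall = cum_tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def confusion_at(sp: ScoredPositions, threshold: float) -> ConfusionCounts:
    """Confusion counts with score ≥ threshold predicting positive."""
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    scores, labels = sp._defined()
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return ConfusionCounts(tp, fp, tn, fn)


def false_positive_positions(sp: ScoredPositions, threshold: float) -> np.ndarray:
    d = sp.df[sp.df["defined"]]
    mask = (d["score"] >= threshold) & (d["label"] == 0)
    return d.loc[mask, "position"].to_numpy()


def proximity_attribution(
    fp_positions: Iterable[int],
    truth_positions: Iterable[int],
    window: int = 7,
) -> AttributionResult:
    """Attribute false positives within ``window`` nt of any true site.

    Distance is the absolute center distance |fp − nearest truth| ≤ window
    (two-sided).  A false positive coinciding with a truth position is a
    labeling inconsistency and is rejected.
    """
    if window < 0:
        raise ValidationError("window must be ≥ 0")
    fps = sorted(int(p) for p in fp_positions)
    truth = np.array(sorted(int(p) for p in truth_positions), dtype=int)
    if set(fps) & set(truth.tolist()):
        raise ValidationError("a false-positive position coincides with a truth position")
    attributed, unattributed = [], []
    for p in fps:
        if truth.size and np.abs(truth - p).min() <= window:
            attributed.append(p)
        else:
            unattributed.append(p)
    return AttributionResult(
        attributed=len(attributed),
        unattributed=len(unattributed),
        attributed_positions=tuple(attributed),
        unattributed_positions=tuple(unattributed),
    )


def summarize(sp: ScoredPositions, threshold: float | None = None,
              proximity_window: int = 7) -> dict:
    """Metric bundle for one score track: AUROC, AUPRC, optional confusion."""
    scores, labels = sp._defined()
    out = {
        "auroc": auroc(sp),
        "auprc": auprc(sp),
        "n_pos": int(labels.sum()),
        "n_neg": int(len(labels) - labels.sum()),
    }
    if threshold is not None:
        cm = confusion_at(sp, threshold)
        attr = proximity_attribution(
            false_positive_positions(sp, threshold),
            sp.df.loc[sp.df["label"] == 1, "position"],
            window=proximity_window,
        )
        out.update(
            threshold=threshold,
            tp=cm.tp, fp=cm.fp, tn=cm.tn, fn=cm.fn,
            fp_attributed=attr.attributed,
            fp_unattributed=attr.unattributed,
        )
    return out
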