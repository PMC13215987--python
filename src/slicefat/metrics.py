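"""Segmentation accuracy metrics: confusion counts, Dice, Hausdorff.

Dice (2*TP / (2*TP + FP + FN)) is the primary overlap metric — robust to
the heavy class imbalance of adipose masks.  The Hausdorff distance is the
symmetric max-min Euclidean distance between the two foreground pixel
coordinate sets, in pixel units; a 95th-percentile variant is available
for robustness to single outlier pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def dice(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 1.0 if denom == 0 else 2 * self.tp / denom


def _check_pair(pred: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs ref {ref.shape}")
    return pred > 0, ref > 0


def confusion(pred: np.ndarray, ref: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts (positive class = adipose)."""
    p, r = _check_pair(pred, ref)
    return ConfusionCounts(
        tp=int(np.sum(p & r)),
        fp=int(np.sum(p & ~r)),
        fn=int(np.sum(~p & r)),
        tn=int(np.sum(~p & ~r)),
    )


def dice(pred: np.ndarray, ref: np.ndarray) -> float:
    """Dice overlap in [0, 1]; both-empty masks score 1.0 by convention."""
    return confusion(pred, ref).dice()


def hausdorff(
    pred: np.ndarray, ref: np.ndarray, percentile: float | None = None
) -> float:
    """Symmetric Hausdorff distance between foreground pixel sets (pixels).

    ``percentile`` (e.g. 95) switches to the percentile variant of the
    directed min-distance distributions; default is the exact maximum.
    """
    p, r = _check_pair(pred, ref)
    a = np.argwhere(p)
    b = np.argwhere(r)
    if a.size == 0 or b.size == 0:
        raise ValueError("Hausdorff distance undefined for an empty mask")
    if percentile is None:
        return max(
            directed_hausdorff(a, b)[0],
            directed_hausdorff(b, a)[0],
        )
    d_ab = cKDTree(b).query(a)[0]
    d_ba = cKDTree(a).query(b)[0]
    return float(
        max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile))
    )


@dataclass(frozen=True)
class CompartmentScore:
    dice: float
    hausdorff_px: float
    confusion: ConfusionCounts

    def __post_init__(self) -> None:
        if abs(self.dice - self.confusion.dice()) > 1e-12:
            raise ValueError("dice inconsistent with confusion counts")


@dataclass(frozen=True)
class EvalReport:
    """Per-compartment scores of an automated result against a reference."""

    method: str
    case_id: str
    scores: dict[str, CompartmentScore]  # keys: tat, sat, vat


def evaluate_compartments(
    pred: dict[str, np.ndarray],
    ref: dict[str, np.ndarray],
    method: str = "",
    case_id: str = "",
) -> EvalReport:
    """Score predicted vs reference masks for each shared compartment."""
    scores = {}
    for name in pred:
        if name not in ref:
            continue
        c = confusion(pred[name], ref[name])
        try:
            hd = hausdorff(pred[name], ref[name])
        except ValueError:
            hd = float("nan")
        scores[name] = CompartmentScore(dice=c.dice(), hausdorff_px=hd, confusion=c)
    return EvalReport(method=method, case_id=case_id, scores=scores)
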