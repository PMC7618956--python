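"""Scoring an unsupervised segmentation against a reference labelling.

The protocol: build the n_Pr x n_RS voxel confusion matrix C between
prediction clusters and reference classes, convert it to a Dice matrix

    D_ij = 2 C_ij / (sum_k C_ik + sum_l C_lj),

then solve the rectangular minimum-weight assignment on the cost -D
(the Hungarian algorithm), which pairs each of the
n_M = min(n_RS, n_Pr) classes one-to-one. The reported score is the
mean of the matched Dice entries. Cluster identities are arbitrary, so
the score is invariant to permuting prediction labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .volume_io import LabelVolume

__all__ = [
    "MatchResult",
    "confusion_matrix",
    "dice_matrix",
    "hungarian_dice",
    "error_map",
    "evaluate_segmentation",
]


@dataclass
class MatchResult:
    """Optimal cluster-to-class assignment and its mean Dice."""

    pairs: list[tuple[int, int]]      # (prediction class, reference class)
    mean_dice: float
    dice: np.ndarray                  # the full Dice matrix


def confusion_matrix(pred: LabelVolume, ref: LabelVolume) -> np.ndarray:
    """C[i, j] = #voxels with prediction label i and reference label j."""
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    n_pr = int(pred.data.max()) + 1
    n_rs = int(ref.data.max()) + 1
    flat = pred.data.ravel().astype(np.int64) * n_rs + ref.data.ravel()
    return np.bincount(flat, minlength=n_pr * n_rs).reshape(n_pr, n_rs)


def dice_matrix(C: np.ndarray) -> np.ndarray:
    """Pairwise Dice from the confusion matrix; 0/0 is defined as 0."""
    C = np.asarray(C, dtype=np.float64)
    if np.any(C < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    denom = C.sum(axis=1, keepdims=True) + C.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(denom > 0, 2.0 * C / denom, 0.0)
    return D


def hungarian_dice(D: np.ndarray) -> MatchResult:
    """Optimal one-to-one matching on cost -D; mean of matched entries.

    The assignment pairs min(n_Pr, n_RS) classes; surplus prediction
    clusters (or reference classes) stay unmatched.
    """
    D = np.asarray(D, dtype=np.float64)
    rows, cols = linear_sum_assignment(-D)
    matched = D[rows, cols]
    return MatchResult(pairs=list(zip(rows.tolist(), cols.tolist())),
                       mean_dice=float(matched.mean()), dice=D)


def error_map(pred: LabelVolume, ref: LabelVolume,
              match: MatchResult) -> LabelVolume:
    """Voxels assigned to a matched cluster but outside its reference class.

    The output labels each such voxel by the 1-based index of its
    (cluster, class) pair; correctly assigned voxels and voxels of
    unmatched prediction clusters are 0.
    """
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    out = np.zeros(pred.shape, dtype=np.int64)
    for idx, (p, r) in enumerate(match.pairs, start=1):
        out[(pred.data == p) & (ref.data != r)] = idx
    return LabelVolume(out)


def evaluate_segmentation(pred: LabelVolume, ref: LabelVolume) -> dict:
    """Convenience wrapper: confusion, Dice, matching, mean Dice."""
    C = confusion_matrix(pred, ref)
    D = dice_matrix(C)
    match = hungarian_dice(D)
    return {
        "confusion": C,
        "dice": D,
        "pairs": match.pairs,
        "mean_dice": match.mean_dice,
    }
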