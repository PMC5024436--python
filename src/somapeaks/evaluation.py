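"""Detection scoring: match predicted against true soma centres, then
compute precision, recall and the F1-measure.

A predicted centre is a true positive when it pairs with a true centre at a
distance strictly below the match threshold (8 um by default).  Pairing is
one-to-one and greedy in ascending distance order, the standard discipline
for centroid-detection evaluation: it prevents one prediction from claiming
several truths and agrees with optimal bipartite matching in all but
adversarial geometries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["EvalResult", "match", "score", "boundary_filter", "evaluate"]

DEFAULT_MATCH_THRESHOLD_UM = 8.0


@dataclass
class EvalResult:
    """Localization scores for one stack."""

    n_true: int
    n_pred: int
    n_true_positive: int
    precision: float
    recall: float
    f1: float
    match_threshold_um: float = DEFAULT_MATCH_THRESHOLD_UM

    def as_dict(self) -> dict:
        return {
            "n_true": self.n_true,
            "n_pred": self.n_pred,
            "n_true_positive": self.n_true_positive,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "match_threshold_um": self.match_threshold_um,
        }


def match(
    true_centers: np.ndarray,
    pred_centers: np.ndarray,
    threshold_um: float = DEFAULT_MATCH_THRESHOLD_UM,
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one pairing of true and predicted centres.

    Candidate pairs are visited in ascending distance order; a pair is kept
    when both endpoints are still free and the distance is strictly below the
    threshold.  Returns ``(true_index, pred_index, distance)`` triples.
    """
    true_centers = np.asarray(true_centers, dtype=float).reshape(-1, 3)
    pred_centers = np.asarray(pred_centers, dtype=float).reshape(-1, 3)
    if len(true_centers) == 0 or len(pred_centers) == 0:
        return []
    D = cdist(true_centers, pred_centers)
    order = np.argsort(D, axis=None, kind="stable")
    used_t = np.zeros(len(true_centers), dtype=bool)
    used_p = np.zeros(len(pred_centers), dtype=bool)
    pairs = []
    for flat in order:
        ti, pi = divmod(int(flat), len(pred_centers))
        if D[ti, pi] >= threshold_um:
            break
        if used_t[ti] or used_p[pi]:
            continue
        used_t[ti] = used_p[pi] = True
        pairs.append((ti, pi, float(D[ti, pi])))
    return pairs


def score(
    n_true_positive: int,
    n_true: int,
    n_pred: int,
    threshold_um: float = DEFAULT_MATCH_THRESHOLD_UM,
) -> EvalResult:
    """Precision, recall and F1 from match counts.

    precision = TP / n_pred, recall = TP / n_true,
    F1 = 2 * precision * recall / (precision + recall); a zero denominator
    yields 0 with a warning.
    """
    if n_true_positive > min(n_true, n_pred):
        raise ValueError("true positives cannot exceed either set size")
    if n_pred == 0 or n_true == 0:
        warnings.warn("empty truth or prediction set: scores are 0", stacklevel=2)
    precision = n_true_positive / n_pred if n_pred else 0.0
    recall = n_true_positive / n_true if n_true else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalResult(
        n_true=n_true,
        n_pred=n_pred,
        n_true_positive=n_true_positive,
        precision=precision,
        recall=recall,
        f1=f1,
        match_threshold_um=threshold_um,
    )


def boundary_filter(
    centers: np.ndarray, extent_um: tuple[float, float, float], margin_um: float
) -> np.ndarray:
    """Drop centres within ``margin_um`` of any stack face.

    ``extent_um`` is the physical stack size per axis; somas near the boundary
    are conventionally excluded from quantification since they may be
    truncated.  ``margin_um = 0`` keeps everything.
    """
    if margin_um < 0:
        raise ValueError("margin must be non-negative")
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    if len(centers) == 0 or margin_um == 0:
        return centers.copy()
    extent = np.asarray(extent_um, dtype=float)
    dist_to_face = np.minimum(centers, extent - centers)
    return centers[(dist_to_face >= margin_um).all(axis=1)]


def evaluate(
    true_centers: np.ndarray,
    pred_centers: np.ndarray,
    threshold_um: float = DEFAULT_MATCH_THRESHOLD_UM,
    extent_um: tuple[float, float, float] | None = None,
    boundary_margin_um: float | None = None,
) -> EvalResult:
    """Match and score in one call; optionally boundary-filter both sets first."""
    true_centers = np.asarray(true_centers, dtype=float).reshape(-1, 3)
    pred_centers = np.asarray(pred_centers, dtype=float).reshape(-1, 3)
    if boundary_margin_um is not None:
        if extent_um is None:
            raise ValueError("boundary filtering needs the stack extent")
        true_centers = boundary_filter(true_centers, extent_um, boundary_margin_um)
        pred_centers = boundary_filter(pred_centers, extent_um, boundary_margin_um)
    pairs = match(true_centers, pred_centers, threshold_um)
    return score(len(pairs), len(true_centers), len(pred_centers), threshold_um)
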