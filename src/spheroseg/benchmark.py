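"""Segmentation evaluation by one-to-one centroid matching.

An automated centroid within the matching radius (default 6 um) of a
ground-truth centroid is a true positive; competition is resolved by a
globally-closest-pair-first greedy assignment, so the result is
deterministic and independent of input ordering.  Unmatched automated
centroids are false positives, unmatched ground-truth centroids false
negatives; precision, recall and F score follow:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F         = 2 * precision * recall / (precision + recall)

Greedy closest-first matching is not guaranteed to reach the maximum
one-to-one matching cardinality, but on realistic centroid sets (spacing
well above the radius) it almost always does; the test suite checks it
against a brute-force maximum matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

DEFAULT_MATCH_RADIUS_UM = 6.0


@dataclass
class MatchReport:
    n_gt: int
    n_auto: int
    TP: int
    FP: int
    FN: int
    precision: float
    recall: float
    f_score: float
    pairs: list[tuple[int, int, float]]   # (gt index, auto index, distance um)
    degenerate: bool = False              # a 0/0 ratio was defined as 0

    def as_dict(self) -> dict:
        return {
            "n_gt": self.n_gt, "n_auto": self.n_auto,
            "TP": self.TP, "FP": self.FP, "FN": self.FN,
            "precision": self.precision, "recall": self.recall,
            "f_score": self.f_score, "degenerate": self.degenerate,
        }


def match_centroids(
    gt: np.ndarray,
    auto: np.ndarray,
    radius: float = DEFAULT_MATCH_RADIUS_UM,
) -> tuple[int, int, int, list[tuple[int, int, float]]]:
    """One-to-one greedy matching of centroid sets in physical um.

    All candidate (gt, auto) pairs within ``radius`` are sorted by
    distance (exact ties broken by lower auto index, then lower gt index)
    and accepted greedily, each index used at most once.  Returns
    ``(TP, FP, FN, pairs)``.
    """
    gt = np.asarray(gt, dtype=float).reshape(-1, 3)
    auto = np.asarray(auto, dtype=float).reshape(-1, 3)
    if len(gt) == 0 or len(auto) == 0:
        return 0, len(auto), len(gt), []

    tree = cKDTree(auto)
    candidates: list[tuple[float, int, int]] = []
    for gi, hits in enumerate(tree.query_ball_point(gt, r=radius)):
        for ai in hits:
            d = float(np.linalg.norm(gt[gi] - auto[ai]))
            candidates.append((d, ai, gi))
    candidates.sort()

    gt_used = np.zeros(len(gt), dtype=bool)
    auto_used = np.zeros(len(auto), dtype=bool)
    pairs: list[tuple[int, int, float]] = []
    for d, ai, gi in candidates:
        if gt_used[gi] or auto_used[ai]:
            continue
        gt_used[gi] = True
        auto_used[ai] = True
        pairs.append((gi, ai, d))
    tp = len(pairs)
    return tp, len(auto) - tp, len(gt) - tp, pairs


def precision_recall_f(tp: int, fp: int, fn: int) -> tuple[float, float, float, bool]:
    """Precision, recall and F score from match counts.

    Any 0/0 ratio is defined as 0 and flagged via the returned
    ``degenerate`` boolean.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    degenerate = False
    if tp + fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f, degenerate = 0.0, True
    else:
        f = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f, degenerate


def evaluate_against_truth(
    auto_centroids: np.ndarray,
    ground_truth,
    radius: float = DEFAULT_MATCH_RADIUS_UM,
) -> MatchReport:
    """Full evaluation of an automated centroid set against ground truth.

    ``ground_truth`` may be a GroundTruth object, an (n, 3) array of
    (x, y, z) um centroids, or a path to a sidecar CSV.
    """
    gt = _resolve_centroids(ground_truth)
    auto = np.asarray(auto_centroids, dtype=float).reshape(-1, 3)
    tp, fp, fn, pairs = match_centroids(gt, auto, radius)
    precision, recall, f, degenerate = precision_recall_f(tp, fp, fn)
    return MatchReport(
        n_gt=len(gt), n_auto=len(auto), TP=tp, FP=fp, FN=fn,
        precision=precision, recall=recall, f_score=f,
        pairs=pairs, degenerate=degenerate,
    )


def _resolve_centroids(ground_truth) -> np.ndarray:
    if isinstance(ground_truth, (str, Path)):
        path = Path(ground_truth)
        if not path.exists():
            raise FileNotFoundError(f"ground-truth sidecar not found: {path}")
        from .synthetic import GroundTruth

        return GroundTruth.load(path).centroids
    if hasattr(ground_truth, "centroids"):
        return np.asarray(ground_truth.centroids, dtype=float).reshape(-1, 3)
    return np.asarray(ground_truth, dtype=float).reshape(-1, 3)


def centroids_of_records(records) -> np.ndarray:
    """(n, 3) um centroid array from a list of NucleusRecord."""
    if not records:
        return np.zeros((0, 3))
    return np.asarray([r.centroid for r in records], dtype=float)
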