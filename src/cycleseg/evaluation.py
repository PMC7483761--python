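"""Per-pixel and object-level precision/recall/F-measure.

Both levels share one formula set:

    precision p = tp / (tp + fp)
    recall    r = tp / (tp + fn)
    F = 2 p r / (p + r)

At the pixel level tp/fp/fn are voxel counts; at the object level they
come from greedy one-to-one matching of detected centroids to annotated
nucleus centers by ascending Euclidean distance, a pair counting as a
true positive when its distance is strictly below the threshold (default
5 voxels). Zero-denominator conventions: a precision or recall whose
denominator is 0 is 1 (nothing claimed / nothing to find); F = 0 when
p + r = 0; the fully empty case scores (1, 1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .postprocess import Detection

__all__ = ["Metrics", "MatchResult", "metrics_from_counts", "pixel_metrics", "match_detections", "object_metrics"]


@dataclass
class Metrics:
    precision: float
    recall: float
    f_measure: float


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    """Matched (detection index, truth index, distance) triples; |pairs| = tp."""


def metrics_from_counts(tp: int, fp: int, fn: int) -> Metrics:
    """Precision/recall/F from raw counts, with the empty conventions."""
    p = tp / (tp + fp) if (tp + fp) > 0 else 1.0
    r = tp / (tp + fn) if (tp + fn) > 0 else 1.0
    f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return Metrics(precision=p, recall=r, f_measure=f)


def pixel_metrics(pred: np.ndarray, truth: np.ndarray) -> Metrics:
    """Voxelwise metrics of a binary prediction against a binary truth."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return metrics_from_counts(tp, fp, fn)


def match_detections(
    detections: list[Detection] | np.ndarray,
    truths: np.ndarray,
    threshold: float = 5.0,
) -> MatchResult:
    """Greedy one-to-one matching of detections to ground-truth points.

    ``detections`` may be Detection objects or an (n, 3) array of (x, y, z)
    centroids; ``truths`` is an (m, 3) array of (x, y, z) centers. Candidate
    pairs are taken in ascending distance order; a pair is accepted when
    both members are unmatched and its distance is strictly below the
    threshold. One-to-one matching keeps the count identities
    tp + fp = #detections and tp + fn = #truths.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if len(detections) and isinstance(detections[0], Detection):
        det = np.array([d.centroid for d in detections], dtype=float)
    else:
        det = np.asarray(detections, dtype=float).reshape(-1, 3)
    tru = np.asarray(truths, dtype=float).reshape(-1, 3)
    n_det, n_tru = len(det), len(tru)
    if n_det == 0 or n_tru == 0:
        return MatchResult(tp=0, fp=n_det, fn=n_tru)
    dist = cdist(det, tru)
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
    det_used = np.zeros(n_det, dtype=bool)
    tru_used = np.zeros(n_tru, dtype=bool)
    pairs: list[tuple[int, int, float]] = []
    for di, ti in order:
        d = dist[di, ti]
        if d >= threshold:
            break
        if not det_used[di] and not tru_used[ti]:
            det_used[di] = tru_used[ti] = True
            pairs.append((int(di), int(ti), float(d)))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=n_det - tp, fn=n_tru - tp, pairs=pairs)


def object_metrics(match: MatchResult) -> Metrics:
    """Precision/recall/F of an object-level match (same formulas as pixel level)."""
    return metrics_from_counts(match.tp, match.fp, match.fn)
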