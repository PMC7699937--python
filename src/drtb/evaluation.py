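"""Detection evaluation: center-distance matching and precision/recall.

A predicted centroid counts as a true positive when it lies within a
distance threshold of a manually annotated stoma center; matching is
one-to-one, greedy by ascending distance. Unmatched annotations are false
negatives, unmatched predictions false positives.

    PPV (precision) = TP / (TP + FP)
    TPR (recall)    = TP / (TP + FN)

A metric with a zero denominator is reported as undefined (None), never as
zero, so that averages over images are not silently deflated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["MatchResult", "Metrics", "match_detections", "precision_recall",
           "aggregate_metrics"]


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list = field(default_factory=list)  # (truth_idx, pred_idx, distance)


@dataclass
class Metrics:
    ppv: Optional[float]
    tpr: Optional[float]


def _as_points(pts) -> np.ndarray:
    arr = np.asarray(pts, dtype=np.float64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of (x, y) points")
    return arr


def match_detections(truth, predictions, radius: float = 30.0) -> MatchResult:
    """One-to-one matching of predictions to annotated centers.

    Candidate pairs with Euclidean distance strictly below ``radius`` are
    assigned greedily by ascending distance; each point participates in at
    most one pair.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    t = _as_points(truth)
    p = _as_points(predictions)
    if t.shape[0] == 0 or p.shape[0] == 0:
        return MatchResult(tp=0, fp=p.shape[0], fn=t.shape[0])
    dmat = cdist(t, p)
    ti, pi = np.nonzero(dmat < radius)
    order = np.argsort(dmat[ti, pi], kind="stable")
    used_t = np.zeros(t.shape[0], dtype=bool)
    used_p = np.zeros(p.shape[0], dtype=bool)
    pairs = []
    for k in order:
        i, j = int(ti[k]), int(pi[k])
        if used_t[i] or used_p[j]:
            continue
        used_t[i] = used_p[j] = True
        pairs.append((i, j, float(dmat[i, j])))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=p.shape[0] - tp, fn=t.shape[0] - tp,
                       pairs=pairs)


def precision_recall(m: MatchResult) -> Metrics:
    """PPV and TPR from the match counts; zero denominators give None."""
    ppv = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else None
    tpr = m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else None
    return Metrics(ppv=ppv, tpr=tpr)


def aggregate_metrics(per_image: Sequence[Metrics]) -> dict:
    """Mean and standard deviation of PPV/TPR across images, ignoring
    undefined values; also reports how many images contributed to each."""
    out = {}
    for name in ("ppv", "tpr"):
        vals = [getattr(m, name) for m in per_image
                if getattr(m, name) is not None]
        if vals:
            out[name] = {"mean": float(np.mean(vals)),
                         "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                         "n_images": len(vals)}
        else:
            out[name] = {"mean": None, "sd": None, "n_images": 0}
    return out
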