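"""Inter-annotator instance-segmentation agreement.

Two annotators' crater masks are compared pairwise: object pairs with a
Jaccard index (intersection over union) strictly greater than the threshold
(default 0.4) are candidate matches, resolved one-to-one greedily by
descending JI.  Matched objects are true positives; unmatched objects in the
first mask are false positives, in the second mask false negatives.  The F1
score is the harmonic mean of the resulting precision and recall, and the
report averages F1 over all annotator pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """|a ∩ b| / |a ∪ b| for two boolean pixel sets; both-empty is an error."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("Jaccard undefined: both sets empty")
    return float(np.logical_and(a, b).sum() / union)


def _pairwise_ji(mask_a: np.ndarray, mask_b: np.ndarray):
    """JI for every overlapping (labelA, labelB) pair via a joint histogram."""
    a = np.asarray(mask_a).ravel()
    b = np.asarray(mask_b).ravel()
    ids_a = np.unique(a[a > 0])
    ids_b = np.unique(b[b > 0])
    sizes_a = {int(i): int((a == i).sum()) for i in ids_a}
    sizes_b = {int(i): int((b == i).sum()) for i in ids_b}
    both = (a > 0) & (b > 0)
    pairs = {}
    if both.any():
        keys = a[both].astype(np.int64) * (b.max() + 1) + b[both].astype(np.int64)
        uniq, cnt = np.unique(keys, return_counts=True)
        for k, c in zip(uniq, cnt):
            ia, ib = int(k // (b.max() + 1)), int(k % (b.max() + 1))
            inter = int(c)
            pairs[(ia, ib)] = inter / (sizes_a[ia] + sizes_b[ib] - inter)
    return pairs, list(map(int, ids_a)), list(map(int, ids_b))


@dataclass
class PairResult:
    tp: int
    fp: int
    fn: int
    matches: list            # (idA, idB, ji)
    ji_values: list          # all overlapping-pair JI values (for the histogram)

    @property
    def precision(self) -> Optional[float]:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def recall(self) -> Optional[float]:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def f1(self) -> Optional[float]:
        p, r = self.precision, self.recall
        if p is None or r is None or (p + r) == 0:
            return 0.0 if (self.fp or self.fn) else None
        return 2 * p * r / (p + r)


@dataclass
class ConcordanceReport:
    pairs: list
    mean_f1: Optional[float]
    ji_threshold: float
    excluded_pairs: int = 0


def match_objects(mask_a: np.ndarray, mask_b: np.ndarray,
                  threshold: float = 0.4, scheme: str = "greedy") -> PairResult:
    """One-to-one matching of instances with JI strictly above the threshold.

    ``scheme='greedy'`` matches by descending JI (ties break toward lower
    ids); ``scheme='optimal'`` maximizes the summed JI over admissible pairs
    with the Hungarian algorithm.  Each object participates in at most one
    match.
    """
    pairs, ids_a, ids_b = _pairwise_ji(mask_a, mask_b)
    admissible = {k: v for k, v in pairs.items() if v > threshold}
    matches = []
    if scheme == "greedy":
        used_a, used_b = set(), set()
        for (ia, ib), ji in sorted(admissible.items(), key=lambda kv: (-kv[1], kv[0])):
            if ia in used_a or ib in used_b:
                continue
            used_a.add(ia)
            used_b.add(ib)
            matches.append((ia, ib, ji))
    elif scheme == "optimal":
        if admissible:
            ra = sorted({k[0] for k in admissible})
            rb = sorted({k[1] for k in admissible})
            cost = np.zeros((len(ra), len(rb)))
            for (ia, ib), ji in admissible.items():
                cost[ra.index(ia), rb.index(ib)] = -ji
            ri, ci = linear_sum_assignment(cost)
            for i, j in zip(ri, ci):
                if cost[i, j] < 0:
                    matches.append((ra[i], rb[j], -cost[i, j]))
    else:
        raise ValueError(f"unknown matching scheme {scheme!r}")
    tp = len(matches)
    fp = len(ids_a) - tp
    fn = len(ids_b) - tp
    return PairResult(tp=tp, fp=fp, fn=fn, matches=matches,
                      ji_values=sorted(pairs.values(), reverse=True))


def f1_report(mask_pairs: Sequence[tuple], threshold: float = 0.4,
              scheme: str = "greedy") -> ConcordanceReport:
    """Per-pair precision/recall/F1 and the arithmetic mean F1 across pairs.

    A pair with no objects on either side has an undefined F1 and is excluded
    from the mean with a warning.
    """
    if len(mask_pairs) == 0:
        raise ValueError("need at least one mask pair")
    results, f1s, excluded = [], [], 0
    for ma, mb in mask_pairs:
        res = match_objects(ma, mb, threshold=threshold, scheme=scheme)
        results.append(res)
        if res.f1 is None:
            excluded += 1
            warnings.warn("pair with zero objects on both sides excluded from mean F1")
        else:
            f1s.append(res.f1)
    mean = float(np.mean(f1s)) if f1s else None
    return ConcordanceReport(pairs=results, mean_f1=mean, ji_threshold=threshold,
                             excluded_pairs=excluded)


def rasterize_annotations(annotations, shape, spacing) -> np.ndarray:
    """Label mask from polygon annotations (um coordinates) on the image grid."""
    import shapely

    sy, sx = spacing
    out = np.zeros(shape, dtype=np.int32)
    yy = np.arange(shape[0]) * sy
    xx = np.arange(shape[1]) * sx
    gy, gx = np.meshgrid(yy, xx, indexing="ij")
    for i, ann in enumerate(annotations, start=1):
        out[shapely.contains_xy(ann.polygon, gy, gx)] = i
    return out
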