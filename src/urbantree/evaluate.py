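"""Inventory accuracy evaluation: point matching and precision/recall/F1.

A suggested tree is compared against the ground-truth inventory with the
candidate-side criteria:

(i)   a candidate is a true positive (TP) iff its nearest truth point is
      strictly closer than the match distance (default 5 m) AND no other
      candidate is closer to that truth point;
(ii)  a candidate within range of a truth point that has a closer candidate,
      or beyond the match distance from every truth point, is a false
      positive (FP);
(iii) a truth point with no candidate within the match distance is a false
      negative (FN).

Note these criteria are candidate-side, not a global assignment: a truth
point can be within range of some candidate yet be neither TP-matched nor FN
(its candidates all won other truth points), so TP + FN may be smaller than
the number of truth points.

The summary statistics are recall r = TP/(TP+FN), precision p = TP/(TP+FP)
and F1 = 2pr/(p+r), reported as percentages rounded half-away-from-zero to
two decimals; F1 is computed from the unrounded p and r.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .core import TreeCandidate, candidate_array

__all__ = [
    "EvalParams",
    "MatchResult",
    "Metrics",
    "match_candidates",
    "compute_metrics",
    "pooled_metrics",
]


@dataclass
class EvalParams:
    match_distance: float = 5.0

    def __post_init__(self) -> None:
        if self.match_distance <= 0:
            raise ValueError("match_distance must be positive")


@dataclass
class MatchResult:
    TP: int
    FP: int
    FN: int
    tp_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(
            self.TP + other.TP,
            self.FP + other.FP,
            self.FN + other.FN,
            self.tp_pairs + other.tp_pairs,
        )


@dataclass
class Metrics:
    """Precision, recall and F1 as percentages (2-decimal, half-up)."""

    p: float
    r: float
    F1: float


def _round2(x: float) -> float:
    # half away from zero, as printed inventories round
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def match_candidates(
    candidates: Sequence[TreeCandidate],
    truth: Sequence[TreeCandidate] | np.ndarray,
    params: EvalParams | None = None,
) -> MatchResult:
    """Apply the matching criteria; ties on distance break by candidate id.

    ``truth`` may be TreeCandidates or an (n, 2) coordinate array (ids then
    default to the row index as a string).  Empty sets are allowed.
    """
    params = params or EvalParams()
    cpos = candidate_array(candidates) if candidates and isinstance(candidates[0], TreeCandidate) else np.asarray(candidates, dtype=float).reshape(-1, 2)
    cids = [c.id for c in candidates] if candidates and isinstance(candidates[0], TreeCandidate) else [str(i) for i in range(len(cpos))]
    if isinstance(truth, np.ndarray) or (len(truth) and not isinstance(truth[0], TreeCandidate)):
        tpos = np.asarray(truth, dtype=float).reshape(-1, 2)
        tids = [str(i) for i in range(len(tpos))]
    else:
        tpos = candidate_array(truth)
        tids = [t.id for t in truth]

    nc, nt = len(cpos), len(tpos)
    if nc == 0:
        return MatchResult(0, 0, nt)
    if nt == 0:
        return MatchResult(0, nc, 0)

    dist = np.sqrt(((cpos[:, None, :] - tpos[None, :, :]) ** 2).sum(-1))

    # nearest truth per candidate, distance ties by truth index order
    nearest_truth = dist.argmin(axis=1)
    # winning candidate per truth: minimal distance, ties broken by candidate id
    id_rank = np.empty(nc, dtype=int)
    id_rank[np.array(sorted(range(nc), key=lambda i: cids[i]))] = np.arange(nc)
    min_d = dist.min(axis=0)
    tied = dist == min_d[None, :]
    win = np.where(tied, id_rank[:, None], nc).argmin(axis=0)

    tp_pairs: list[tuple[str, str, float]] = []
    TP = 0
    for i in range(nc):
        g = int(nearest_truth[i])
        if dist[i, g] < params.match_distance and win[g] == i:
            TP += 1
            tp_pairs.append((cids[i], tids[g], float(dist[i, g])))
    FP = nc - TP
    FN = int(np.sum(dist.min(axis=0) >= params.match_distance))

    result = MatchResult(TP, FP, FN, tp_pairs)
    assert result.TP + result.FP == nc
    assert result.TP + result.FN <= nt
    return result


def compute_metrics(mr: MatchResult) -> Metrics:
    """Precision/recall/F1 percentages from match counts.

    Zero denominators (and TP = 0 overall) yield 0 by convention.  F1 is
    computed from the unrounded precision and recall, then rounded — rounding
    first would corrupt the second decimal.
    """
    p = 100.0 * mr.TP / (mr.TP + mr.FP) if mr.TP + mr.FP else 0.0
    r = 100.0 * mr.TP / (mr.TP + mr.FN) if mr.TP + mr.FN else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return Metrics(p=_round2(p), r=_round2(r), F1=_round2(f1))


def pooled_metrics(per_zone: Sequence[MatchResult]) -> Metrics:
    """Pool TP/FP/FN across zones, then compute the metrics once."""
    if not per_zone:
        raise ValueError("need at least one zone")
    total = MatchResult(0, 0, 0)
    for mr in per_zone:
        total = total + mr
    return compute_metrics(total)
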