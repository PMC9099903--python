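"""Merging of nearby tree candidates (buffer-union procedure).

Applied after every pipeline stage: candidates closer than ``merge_distance``
(default 4 m) are artifacts of the same tree — branches throwing several local
maxima, or one tree located from several panoramas — and are collapsed to a
single candidate.  Realized as circular buffers of radius merge_distance / 2
around each point; buffers that intersect (centers strictly closer than
merge_distance; tangency does not merge) form connected components, and each
component is replaced by one candidate at its centroid.

A single pass can leave centroids of chained components closer than the
threshold again, so by default merging is iterated to a fixed point (bounded
by n passes); ``single_pass`` gives the strict one-shot behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from shapely.geometry import Point
from shapely.ops import unary_union

from .core import TreeCandidate, candidate_array

__all__ = ["MergeParams", "merge_candidates"]


@dataclass
class MergeParams:
    merge_distance: float = 4.0
    position_rule: str = "point_centroid"  # or "polygon_centroid"
    single_pass: bool = False

    def __post_init__(self) -> None:
        if self.merge_distance <= 0:
            raise ValueError("merge_distance must be positive")
        if self.position_rule not in ("point_centroid", "polygon_centroid"):
            raise ValueError("position_rule must be point_centroid or polygon_centroid")


def _merge_once(
    candidates: Sequence[TreeCandidate], params: MergeParams
) -> tuple[list[TreeCandidate], dict[str, list[str]]]:
    pts = candidate_array(candidates)
    n = len(candidates)
    tree = cKDTree(pts)
    # strict inequality: centers exactly merge_distance apart (tangent
    # buffers) are NOT merged
    pairs = tree.query_pairs(params.merge_distance, output_type="ndarray")
    if len(pairs):
        d = np.sqrt(((pts[pairs[:, 0]] - pts[pairs[:, 1]]) ** 2).sum(1))
        pairs = pairs[d < params.merge_distance]
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]]) if len(pairs) else np.empty(0, int)
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]]) if len(pairs) else np.empty(0, int)
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)

    merged: list[TreeCandidate] = []
    membership: dict[str, list[str]] = {}
    for comp in range(n_comp):
        idx = np.nonzero(labels == comp)[0]
        members = [candidates[i] for i in idx]
        if len(members) == 1:
            merged.append(members[0])
            continue
        if params.position_rule == "point_centroid":
            cx, cy = pts[idx].mean(axis=0)
        else:
            union = unary_union(
                [Point(p).buffer(params.merge_distance / 2.0, quad_segs=64) for p in pts[idx]]
            )
            cx, cy = union.centroid.x, union.centroid.y
        heights = [m.height for m in members if m.height is not None]
        member_ids = sorted(m.id for m in members)
        new_id = "m(" + "+".join(member_ids) + ")"
        merged.append(
            TreeCandidate(
                id=new_id,
                x=float(cx),
                y=float(cy),
                height=max(heights) if heights else None,
                source="merged",
            )
        )
        membership[new_id] = member_ids
    return merged, membership


def merge_candidates(
    candidates: Sequence[TreeCandidate],
    params: MergeParams | None = None,
    return_membership: bool = False,
):
    """Collapse candidates closer than ``merge_distance`` into centroids.

    Component height is the max member height (when any member has one); the
    merged id is deterministic from the sorted member ids.  Iterates until no
    two output centroids are closer than the threshold unless ``single_pass``.

    With ``return_membership`` also returns {merged id: [member ids]} from the
    final pass structure (singletons omitted).
    """
    params = params or MergeParams()
    current = list(candidates)
    membership: dict[str, list[str]] = {}
    for _ in range(max(len(current), 1)):
        merged, step = _merge_once(current, params) if current else ([], {})
        # compose membership through passes down to original ids
        for new_id, mids in step.items():
            flat: list[str] = []
            for mid in mids:
                flat.extend(membership.pop(mid, [mid]))
            membership[new_id] = sorted(flat)
        if len(merged) == len(current):
            current = merged
            break
        current = merged
        if params.single_pass:
            break
    if return_membership:
        return current, membership
    return current
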