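"""Grouping co-eluting features into feature sets.

Ions from one compound (its adducts, isotopologues and in-source
fragments) elute together, so their chromatographic profiles coincide.
Pairs of features are connected when their characteristic retention times
agree within ``rt_tol`` AND the normalized inner product (cosine) of
their elution profiles, resampled onto the union of their time grids over
the overlap, passes ``min_similarity``.  Connected components of that
graph (single linkage, so transitive adduct/isotope chains stay together)
become :class:`~lcmspipe.model.FeatureSet` objects at the mean member rt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import Feature, FeatureSet

__all__ = ["GroupingParams", "profile_inner_product", "group_features"]


@dataclass(frozen=True)
class GroupingParams:
    rt_tol: float = 5.0
    min_similarity: float = 0.9

    def __post_init__(self) -> None:
        if self.rt_tol <= 0:
            raise ValueError("rt_tol must be positive")
        if not 0.0 <= self.min_similarity <= 1.0:
            raise ValueError("min_similarity must be in [0, 1]")


def profile_inner_product(a: Feature, b: Feature) -> float:
    """Cosine similarity of two elution profiles on their shared time window.

    Both traces are linearly interpolated onto the union of their scan
    times restricted to the overlap of their spans.  Disjoint spans or an
    all-zero trace give 0; identical (or positively proportional) traces
    give 1.
    """
    lo = max(a.times[0], b.times[0])
    hi = min(a.times[-1], b.times[-1])
    if lo > hi:
        return 0.0
    grid = np.union1d(a.times, b.times)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size == 0:
        return 0.0
    va = np.interp(grid, a.times, a.intensities)
    vb = np.interp(grid, b.times, b.intensities)
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(min(1.0, np.dot(va, vb) / (na * nb)))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def group_features(features: Sequence[Feature],
                   params: GroupingParams = GroupingParams()) -> list[FeatureSet]:
    """Partition features of one sample into co-elution feature sets.

    Single-linkage clustering on the graph whose edges connect pairs with
    |delta rt| <= ``rt_tol`` and profile inner product >=
    ``min_similarity``.  Every input feature lands in exactly one output
    set; singletons become singleton sets.  Mixed ion modes are rejected.
    """
    features = list(features)
    if not features:
        return []
    if len({f.ion_mode for f in features}) > 1:
        raise ValueError("group_features requires a single ion mode")

    n = len(features)
    order = sorted(range(n), key=lambda i: features[i].rt)
    uf = _UnionFind(n)
    for a_pos in range(n):
        i = order[a_pos]
        for b_pos in range(a_pos + 1, n):
            j = order[b_pos]
            if features[j].rt - features[i].rt > params.rt_tol:
                break
            if profile_inner_product(features[i], features[j]) >= params.min_similarity:
                uf.union(i, j)

    components: dict[int, list[Feature]] = {}
    for i in range(n):
        components.setdefault(uf.find(i), []).append(features[i])
    sets = []
    for members in components.values():
        members.sort(key=lambda f: f.mz)
        rt = sum(f.rt for f in members) / len(members)
        sets.append(FeatureSet(id=len(sets), features=tuple(members), rt=rt))
    sets.sort(key=lambda fs: fs.rt)
    return [FeatureSet(id=i, features=fs.features, rt=fs.rt,
                       neutral_mass=fs.neutral_mass) for i, fs in enumerate(sets)]
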