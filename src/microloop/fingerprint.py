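"""DGGE fingerprint analytics: band matrices, commonality, clustering.

A quantified gel reduces to lanes of (position, peak surface) bands.
Bands are aligned across lanes by position, each band's relative
intensity is P_i = n_i / N (surface over lane total), treatments are
compared by which aligned bands they contain, and lanes are clustered by
UPGMA on Bray–Curtis dissimilarity of the relative-intensity profiles —
the standard fingerprint workflow for community structure comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from skbio.tree import TreeNode

from .datatypes import BandMatrix, TREATMENTS
from .errors import InputError

DEFAULT_TOLERANCE_PX = 5.0


def relative_intensity(surfaces: Sequence[float]) -> np.ndarray:
    """P_i = n_i / N for one lane's peak surfaces (absent bands stay 0)."""
    arr = np.asarray(surfaces, dtype=float)
    if np.any(arr < 0):
        raise InputError("peak surfaces must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise InputError("lane has no positive peak surface")
    return arr / total


def match_bands(raw_lanes: Mapping[str, Sequence[tuple[float, float]]],
                tolerance: float = DEFAULT_TOLERANCE_PX) -> BandMatrix:
    """Align bands across lanes by greedy nearest-position clustering.

    Bands (from any lane) within ``tolerance`` pixels of a cluster's
    running mean position belong to the same canonical band; the
    canonical position is the mean of the members. The sweep runs in
    ascending position order (ties broken toward the lower position,
    then lane order), so the result is deterministic. Two bands from
    the same lane cannot share a canonical band.
    """
    if tolerance <= 0:
        raise InputError("tolerance must be > 0")
    lanes = list(raw_lanes)
    flat = []
    for lane_idx, lane in enumerate(lanes):
        for pos, surface in raw_lanes[lane]:
            if surface <= 0:
                raise InputError(f"non-positive band surface in lane {lane!r}")
            flat.append((float(pos), lane_idx, float(surface)))
    if not flat:
        raise InputError("no bands to match")
    flat.sort(key=lambda rec: (rec[0], rec[1]))
    clusters: list[dict] = []
    for pos, lane_idx, surface in flat:
        cur = clusters[-1] if clusters else None
        if cur is not None and abs(pos - cur["mean"]) <= tolerance:
            if lane_idx in cur["members"]:
                raise InputError(
                    f"two bands from lane {lanes[lane_idx]!r} map to one "
                    f"canonical band near {cur['mean']:.1f} px")
            cur["members"][lane_idx] = surface
            cur["positions"].append(pos)
            cur["mean"] = float(np.mean(cur["positions"]))
        else:
            clusters.append({"mean": pos, "positions": [pos],
                             "members": {lane_idx: surface}})
    intensity = np.zeros((len(lanes), len(clusters)))
    for j, cluster in enumerate(clusters):
        for lane_idx, surface in cluster["members"].items():
            intensity[lane_idx, j] = surface
    positions = np.array([c["mean"] for c in clusters])
    return BandMatrix(lanes=lanes, positions=positions, intensity=intensity)


@dataclass(frozen=True)
class CommonalityTable:
    """Band-sharing tallies across the three treatments.

    Counts partition the total: bands in all three treatments, bands
    specific to one treatment, and bands shared by exactly one pair.
    Percentages are of the total band count, rounded to integers.
    """

    total: int
    treatment_counts: dict
    common: int
    specific: dict  # treatment -> count
    pairs: dict  # frozenset pair -> count

    @property
    def common_pct(self) -> int:
        return _pct(self.common, self.total)

    def specific_pct(self, treatment: str) -> int:
        return _pct(self.specific[treatment], self.total)

    def pair_count(self, a: str, b: str) -> int:
        return self.pairs.get(frozenset((a, b)), 0)

    def pair_pct(self, a: str, b: str) -> int:
        return _pct(self.pair_count(a, b), self.total)

    def check_partition(self) -> bool:
        return (self.common + sum(self.specific.values())
                + sum(self.pairs.values()) == self.total)

    def to_frame(self) -> pd.DataFrame:
        rows = [("total bands", self.total, 100)]
        rows.append(("common to all treatments", self.common,
                     self.common_pct))
        for t in sorted(self.specific):
            rows.append((f"specific to {t}", self.specific[t],
                         self.specific_pct(t)))
        for pair in sorted(self.pairs, key=sorted):
            a, b = sorted(pair)
            rows.append((f"shared by {a}+{b} only", self.pairs[pair],
                         self.pair_pct(a, b)))
        return pd.DataFrame(rows, columns=["category", "count", "percent"])


def _pct(count: int, total: int) -> int:
    # round half away from zero, the convention of the reported tallies
    return int(math.floor(100.0 * count / total + 0.5))


def commonality_table(matrix: BandMatrix,
                      lane_to_treatment: Mapping[str, str],
                      detection_floor: float = 0.0) -> CommonalityTable:
    """Tally band sharing between treatments.

    A band belongs to a treatment if its relative intensity exceeds
    ``detection_floor`` in any lane mapped to that treatment (lanes may
    include both t0 and t_final per treatment).
    """
    for lane in matrix.lanes:
        if lane not in lane_to_treatment:
            raise InputError(f"lane {lane!r} not mapped to a treatment")
    treatments = sorted(set(lane_to_treatment.values()),
                        key=TREATMENTS.index)
    if len(treatments) < 3:
        raise InputError("all three treatments must be represented")
    rel = matrix.relative_intensity
    presence = {}
    for treatment in treatments:
        lane_rows = [matrix.lanes.index(l) for l in matrix.lanes
                     if lane_to_treatment[l] == treatment]
        presence[treatment] = (rel[lane_rows] > detection_floor).any(axis=0)
    n_bands = matrix.positions.size
    common = 0
    specific = {t: 0 for t in treatments}
    pairs: dict[frozenset, int] = {}
    treatment_counts = {t: int(presence[t].sum()) for t in treatments}
    for j in range(n_bands):
        members = [t for t in treatments if presence[t][j]]
        if len(members) == len(treatments):
            common += 1
        elif len(members) == 1:
            specific[members[0]] += 1
        elif len(members) == 2:
            key = frozenset(members)
            pairs[key] = pairs.get(key, 0) + 1
    return CommonalityTable(total=n_bands,
                            treatment_counts=treatment_counts,
                            common=common, specific=specific, pairs=pairs)


def bray_curtis_similarity(p: Sequence[float], q: Sequence[float]) -> float:
    """1 − Σ|p_i − q_i| / Σ(p_i + q_i) on a shared matched band set."""
    pa = np.asarray(p, dtype=float)
    qa = np.asarray(q, dtype=float)
    if pa.shape != qa.shape:
        raise InputError("profiles must share the matched band set")
    if np.any(pa < 0) or np.any(qa < 0):
        raise InputError("relative intensities must be non-negative")
    denom = (pa + qa).sum()
    if denom == 0:
        raise InputError("Bray-Curtis undefined for two all-zero profiles")
    return float(1.0 - np.abs(pa - qa).sum() / denom)


def similarity_matrix(matrix: BandMatrix) -> pd.DataFrame:
    """Pairwise Bray–Curtis similarity between all lanes."""
    rel = matrix.relative_intensity
    n = len(matrix.lanes)
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = bray_curtis_similarity(rel[i], rel[j])
    return pd.DataFrame(sim, index=matrix.lanes, columns=matrix.lanes)


def linkage_matrix(matrix: BandMatrix) -> np.ndarray:
    """UPGMA (average) linkage on Bray–Curtis dissimilarity."""
    if len(matrix.lanes) < 2:
        raise InputError("need at least 2 lanes to cluster")
    dist = pdist(matrix.relative_intensity, metric="braycurtis")
    return hierarchy.linkage(dist, method="average")


def cluster_lanes(matrix: BandMatrix) -> TreeNode:
    """UPGMA dendrogram of lanes, serializable as newick.

    Agglomeration order is deterministic: exact ties in the
    dissimilarity merge in lane (input) order.
    """
    link = linkage_matrix(matrix)
    tree = TreeNode.from_linkage_matrix(link, matrix.lanes)
    return tree


def cut_clusters(matrix: BandMatrix, n_clusters: int) -> dict[str, int]:
    """Flat cluster labels for each lane at a requested cluster count."""
    link = linkage_matrix(matrix)
    labels = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    return dict(zip(matrix.lanes, (int(x) for x in labels)))
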