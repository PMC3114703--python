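"""Fingerprint analytics: P_i, band matching, commonality, clustering."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microloop import (BandMatrix, InputError, bray_curtis_similarity,
                       cluster_lanes, commonality_table, match_bands,
                       relative_intensity, similarity_matrix, simulate_gel,
                       simulate_lane_bands)
from microloop.fingerprint import cut_clusters, linkage_matrix
from microloop.simulate import partition_profiles

LANE_MAP = {"V": "V", "VF": "VF", "VFA": "VFA"}


class TestRelativeIntensity:
    @pytest.mark.parametrize("surfaces,expected", [
        ([2, 3, 5], [0.2, 0.3, 0.5]),
        ([1, 1, 1, 1], [0.25] * 4),
        ([1, 0, 7, 2], [0.1, 0.0, 0.7, 0.2]),
    ])
    def test_normalization(self, surfaces, expected):
        np.testing.assert_allclose(relative_intensity(surfaces), expected)

    def test_all_zero_lane_rejected(self):
        with pytest.raises(InputError):
            relative_intensity([0.0, 0.0])


class TestMatchBands:
    def test_identical_lanes_match_band_for_band(self):
        lanes = {"A": [(100.0, 5.0), (150.0, 3.0)],
                 "B": [(100.0, 2.0), (150.0, 9.0)]}
        bm = match_bands(lanes, tolerance=5)
        assert bm.positions.tolist() == [100.0, 150.0]
        assert (bm.intensity > 0).all()

    def test_nearby_bands_merge_at_mean_position(self):
        bm = match_bands({"A": [(100.0, 1.0)], "B": [(104.0, 1.0)]},
                         tolerance=5)
        assert bm.positions.tolist() == [102.0]

    def test_same_lane_conflict_raises(self):
        with pytest.raises(InputError, match="canonical band"):
            match_bands({"A": [(100.0, 1.0), (103.0, 1.0)]}, tolerance=5)

    def test_recovers_true_band_count_under_jitter(self):
        """Jittered lanes (sd 1 px, canonical spacing 10 px) realign."""
        profiles = {f"L{i}": np.full(12, 1 / 12) for i in range(3)}
        raw = simulate_lane_bands(profiles, position_jitter=1.0, seed=42)
        bm = match_bands(raw, tolerance=5)
        assert bm.positions.size == 12

    def test_idempotent(self):
        profiles = {f"L{i}": np.full(8, 1 / 8) for i in range(3)}
        raw = simulate_lane_bands(profiles, position_jitter=1.0, seed=7)
        bm = match_bands(raw, tolerance=5)
        again = match_bands(
            {lane: [(p, s) for p, s in zip(bm.positions, bm.intensity[i])
                    if s > 0]
             for i, lane in enumerate(bm.lanes)}, tolerance=5)
        np.testing.assert_allclose(again.positions, bm.positions)
        np.testing.assert_allclose(again.intensity, bm.intensity)


class TestCommonality:
    def test_all_lanes_identical_is_fully_common(self):
        profiles = {t: np.full(10, 0.1) for t in ("V", "VF", "VFA")}
        bm = simulate_gel(profiles)
        table = commonality_table(bm, LANE_MAP)
        assert table.common == table.total == 10
        assert table.common_pct == 100
        assert all(v == 0 for v in table.specific.values())

    def test_partition_identity_holds(self):
        tallies = {"total": 31, "common": 13, "V": 1, "VF": 2, "VFA": 2,
                   "VFA+VF": 2}
        bm = simulate_gel(partition_profiles(tallies))
        table = commonality_table(bm, LANE_MAP)
        assert table.check_partition()
        assert table.common == 13
        assert table.common_pct == 42  # 13/31

    def test_pair_specific_tally(self):
        tallies = {"total": 31, "common": 13, "V": 1, "VF": 0, "VFA": 1,
                   "VFA+VF": 7}
        bm = simulate_gel(partition_profiles(tallies))
        table = commonality_table(bm, LANE_MAP)
        assert table.pair_count("VFA", "VF") == 7
        assert table.pair_pct("VFA", "VF") == 23  # 7/31

    def test_unmapped_lane_rejected(self):
        profiles = {t: np.full(4, 0.25) for t in ("V", "VF", "VFA")}
        bm = simulate_gel(profiles)
        with pytest.raises(InputError):
            commonality_table(bm, {"V": "V", "VF": "VF"})


class TestBrayCurtis:
    def test_identical_profiles_similarity_one(self):
        p = [0.2, 0.3, 0.5]
        assert bray_curtis_similarity(p, p) == pytest.approx(1.0)

    def test_disjoint_profiles_similarity_zero(self):
        assert bray_curtis_similarity([0.5, 0.5, 0, 0],
                                      [0, 0, 0.5, 0.5]) == 0.0

    def test_hand_value(self):
        assert bray_curtis_similarity([0.5, 0.5, 0.0],
                                      [0.25, 0.25, 0.5]) == \
            pytest.approx(0.5)

    @given(st.lists(st.floats(0, 1), min_size=3, max_size=6),
           st.lists(st.floats(0, 1), min_size=3, max_size=6))
    @settings(max_examples=50, derandomize=True)
    def test_symmetric_and_bounded(self, p, q):
        n = min(len(p), len(q))
        p, q = p[:n], q[:n]
        if sum(p) + sum(q) == 0:
            return
        s = bray_curtis_similarity(p, q)
        assert 0.0 <= s <= 1.0 + 1e-12
        assert s == pytest.approx(bray_curtis_similarity(q, p))


def upgma_cophenetic_oracle(dist: np.ndarray) -> np.ndarray:
    """Brute-force UPGMA: merge closest clusters, average original dist."""
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for (i, a), (j, b) in itertools.combinations(
                enumerate(clusters), 2):
            d = np.mean([dist[x, y] for x in a for y in b])
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        for x in clusters[i]:
            for y in clusters[j]:
                coph[x, y] = coph[y, x] = d
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return coph


class TestClusterLanes:
    def test_identical_pair_joins_first(self):
        p = np.full(6, 1 / 6)
        q = np.zeros(6)
        q[:2] = 0.5
        bm = simulate_gel({"A": p, "B": p, "C": q}, detection_floor=0.0)
        tree = cluster_lanes(bm)
        tips = sorted(x.name for x in tree.find("A").parent.tips())
        assert tips == ["A", "B"]

    def test_cophenetic_matches_brute_force_upgma(self, rng):
        """Cophenetic distances equal the from-scratch agglomeration."""
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import pdist, squareform
        profiles = {f"L{i}": relative_intensity(rng.random(8))
                    for i in range(5)}
        bm = BandMatrix(lanes=list(profiles),
                        positions=np.arange(8, dtype=float),
                        intensity=np.vstack(list(profiles.values())))
        link = linkage_matrix(bm)
        got = squareform(cophenet(link))
        dist = squareform(pdist(bm.relative_intensity,
                                metric="braycurtis"))
        expected = upgma_cophenetic_oracle(dist)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_planted_two_group_partition_recovered(self):
        group1 = relative_intensity([1, 1, 1, 1, 0, 0, 0, 0])
        group2 = relative_intensity([0, 0, 0, 0, 1, 1, 1, 1])
        jitters = {"A1": 0.0, "A2": 0.01, "B1": 0.0, "B2": 0.01}
        profiles = {}
        for lane, eps in jitters.items():
            base = group1 if lane.startswith("A") else group2
            perturbed = base + eps
            profiles[lane] = perturbed / perturbed.sum()
        bm = simulate_gel(profiles, detection_floor=0.0)
        labels = cut_clusters(bm, 2)
        assert labels["A1"] == labels["A2"]
        assert labels["B1"] == labels["B2"]
        assert labels["A1"] != labels["B1"]

    def test_single_lane_rejected(self):
        bm = simulate_gel({"A": np.full(4, 0.25)})
        with pytest.raises(InputError):
            cluster_lanes(bm)

    def test_similarity_matrix_diagonal_and_symmetry(self):
        profiles = {t: relative_intensity(np.arange(1, 6, dtype=float))
                    for t in ("V", "VF")}
        profiles["VFA"] = relative_intensity([5, 4, 3, 2, 1.0])
        bm = simulate_gel(profiles)
        sim = similarity_matrix(bm)
        assert np.allclose(np.diag(sim), 1.0)
        assert np.allclose(sim, sim.T)
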