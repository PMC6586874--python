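"""Adaptive binning and the quadratic-form dissimilarity metric."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytoqf import adaptive_bin, bin_cluster, qf_distance, similarity_matrix
from cytoqf.errors import EmptyInputError
from cytoqf.qf_core import bin_depth


def brute_force_qf(f, g, a):
    """Independent double-loop evaluation of the quadratic form."""
    diff = np.asarray(f) - np.asarray(g)
    total = 0.0
    for i in range(len(diff)):
        for j in range(len(diff)):
            total += diff[i] * diff[j] * a[i, j]
    return np.sqrt(max(0.0, total))


def random_histograms(rng, b):
    f = rng.dirichlet(np.ones(b))
    g = rng.dirichlet(np.ones(b))
    cent = rng.normal(size=(b, 3))
    d = np.linalg.norm(cent[:, None] - cent[None, :], axis=-1)
    a = 1.0 - d / d.max()
    return f, g, a


class TestBinDepth:
    @pytest.mark.parametrize(
        "n_a,n_b,expected_B",
        [
            (1000, 1000, 128),  # L = round(log2(2000/13.8)) = 7
            (4, 4, 4),  # L = round(log2(8/2.77)) = 2
        ],
    )
    def test_stated_arithmetic(self, n_a, n_b, expected_B):
        assert 2 ** bin_depth(n_a + n_b, min(n_a, n_b)) == expected_B

    def test_depth_floored_at_zero(self):
        # fewer merged events than the per-bin target -> a single bin
        assert bin_depth(10, 150) == 0


class TestAdaptiveBin:
    def test_partition_property(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(1000, 3)), rng.normal(2.0, 1.0, size=(800, 3))
        binning = adaptive_bin(a, b)
        assert binning.B == 2**binning.depth
        for sample in (a, b):
            bins = binning.assign(sample)
            assert bins.min() >= 0 and bins.max() < binning.B
            assert len(bins) == len(sample)

    def test_occupancy_near_target(self):
        """Mean occupancy within a factor of 2 of 2*ln(n_small); every merged
        bin holds at least one and at most 4x the target."""
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(3000, 3)), rng.normal(size=(2000, 3))
        binning = adaptive_bin(a, b)
        target = 2 * np.log(2000)
        counts = np.bincount(binning.assign(np.vstack([a, b])), minlength=binning.B)
        mean_occ = counts.mean()
        assert target / 2 <= mean_occ <= 2 * target
        assert counts.min() >= 1
        assert counts.max() <= 4 * target

    def test_empty_sample_rejected(self):
        with pytest.raises(EmptyInputError):
            adaptive_bin(np.empty((0, 2)), np.ones((5, 2)))

    def test_boundary_tie_rule(self):
        """Events exactly at a median threshold go to the right child."""
        a = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        binning = adaptive_bin(a, a, depth=1)
        thr = binning.root.threshold
        bins = binning.assign(np.array([[thr, 0.0], [thr - 1e-9, 0.0]]))
        left_bin = binning.root.left.bin_index
        right_bin = binning.root.right.bin_index
        assert bins[0] == right_bin and bins[1] == left_bin


class TestBinCluster:
    def test_point_mass(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(500, 2))
        binning = adaptive_bin(a, a)
        one = bin_cluster(binning, np.array([[0.0, 0.0]]))
        assert one.frequencies.sum() == pytest.approx(1.0)
        assert np.count_nonzero(one.frequencies) == 1

    def test_whole_sample_consistency(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(600, 2)), rng.normal(size=(600, 2))
        binning = adaptive_bin(a, b)
        merged = np.vstack([a, b])
        freq = bin_cluster(binning, merged).frequencies
        counts = np.bincount(binning.assign(merged), minlength=binning.B)
        np.testing.assert_allclose(freq, counts / counts.sum(), atol=1e-12)
        assert freq.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_cluster_rejected(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(500, 2))
        binning = adaptive_bin(a, a)
        with pytest.raises(EmptyInputError):
            bin_cluster(binning, a, np.array([], dtype=int))


class TestQFDistance:
    def test_identity(self):
        rng = np.random.default_rng(5)
        f, _, a = random_histograms(rng, 8)
        assert qf_distance(f, f, a) == 0.0

    def test_hand_evaluated_two_bin_case(self):
        """B=2, f=(1,0), g=(0,1), centroids 1 apart -> A=I -> sqrt(2)."""
        a = np.eye(2)
        assert qf_distance(
            np.array([1.0, 0.0]), np.array([0.0, 1.0]), a
        ) == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        for b in (3, 5, 16):
            f, g, a = random_histograms(rng, b)
            assert qf_distance(f, g, a) == pytest.approx(
                brute_force_qf(f, g, a), abs=1e-12
            )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            qf_distance(np.ones(3) / 3, np.ones(4) / 4, np.eye(3))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_metric_axioms(self, seed):
        """Nonnegativity, symmetry, identity, triangle inequality on random
        histogram triples."""
        rng = np.random.default_rng(seed)
        b = int(rng.integers(2, 10))
        f, g, a = random_histograms(rng, b)
        h = rng.dirichlet(np.ones(b))
        dfg = qf_distance(f, g, a)
        assert dfg >= 0
        assert dfg == pytest.approx(qf_distance(g, f, a), abs=1e-12)
        assert qf_distance(f, f, a) == pytest.approx(0.0, abs=1e-12)
        assert dfg <= qf_distance(f, h, a) + qf_distance(h, g, a) + 1e-9

    def test_monotone_in_centroid_distance(self):
        """Moving g's mass to farther bins along a centroid line increases
        the dissimilarity from f concentrated at bin 0."""
        b = 6
        cent = np.column_stack([np.arange(b, dtype=float), np.zeros(b)])
        d = np.abs(cent[:, :1] - cent[:, :1].T)
        a = 1.0 - d / d.max()
        f = np.zeros(b)
        f[0] = 1.0
        prev = -1.0
        for k in range(1, b):
            g = np.zeros(b)
            g[k] = 1.0
            cur = qf_distance(f, g, a)
            assert cur > prev
            prev = cur


class TestSimilarityMatrix:
    def test_invariants(self):
        rng = np.random.default_rng(7)
        a_events = rng.normal(size=(500, 3))
        b_events = rng.normal(1.0, 1.0, size=(400, 3))
        binning = adaptive_bin(a_events, b_events)
        a = similarity_matrix(binning)
        assert np.allclose(np.diag(a), 1.0)
        assert np.allclose(a, a.T)
        assert a.min() >= 0.0 and a.max() <= 1.0
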