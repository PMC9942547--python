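"""Partition metrics, isotope-pair machinery and vectorization baselines."""

import itertools

import numpy as np
import pytest

from mzclust.data_model import IonImageStack
from mzclust.metrics import (
    IsotopePairSet,
    UndefinedMetricError,
    ari,
    clustering_accuracy,
    detect_isotope_pairs,
    gmm_baseline,
    isotope_ratio,
    kmeans_baseline,
    nmi,
    relative_isotope_ratio,
)


def brute_force_acc(truth, pred):
    """Max fraction correct over all label permutations (k small)."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    t_ids = np.unique(truth)
    p_ids = np.unique(pred)
    ids = np.union1d(t_ids, p_ids)
    best = 0.0
    for perm in itertools.permutations(ids):
        mapping = dict(zip(ids, perm))
        remapped = np.array([mapping[p] for p in pred])
        best = max(best, np.mean(remapped == truth))
    return best


class TestClusteringAccuracy:
    def test_perfect(self):
        assert clustering_accuracy([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_relabeling_invariance(self):
        truth = [0, 0, 1, 1, 2, 2]
        assert clustering_accuracy(truth, [2, 2, 0, 0, 1, 1]) == 1.0

    def test_small_example(self):
        assert clustering_accuracy([0, 0, 1, 1], [0, 1, 1, 1]) == 0.75

    def test_matches_brute_force_on_random_partitions(self):
        rng = np.random.default_rng(0)
        for k in (2, 3, 4, 5, 6):
            truth = rng.integers(0, k, size=40)
            pred = rng.integers(0, k, size=40)
            assert clustering_accuracy(truth, pred) == pytest.approx(
                brute_force_acc(truth, pred)
            )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            clustering_accuracy([0, 1], [0, 1, 2])


class TestNmiAri:
    def test_identical_partitions(self):
        labels = [0, 1, 2, 0, 1, 2]
        assert nmi(labels, labels) == pytest.approx(1.0)
        assert ari(labels, labels) == pytest.approx(1.0)

    def test_single_cluster_is_chance(self):
        truth = [0, 0, 1, 1]
        assert ari(truth, [0, 0, 0, 0]) == pytest.approx(0.0)

    def test_contingency_closed_form(self):
        """truth=[0,0,0,1], pred=[0,0,1,1]: contingency [[2,1],[0,1]]."""
        truth = [0, 0, 0, 1]
        pred = [0, 0, 1, 1]
        # ARI by hand: sum_ij C(n_ij,2)=1, sum_a C(a,2)=3, sum_b C(b,2)=2,
        # expected=3*2/C(4,2)=1, max=(3+2)/2=2.5 -> (1-1)/(2.5-1)=0
        assert ari(truth, pred) == pytest.approx(0.0)
        # NMI by hand: H(T)=H(0.75,0.25), H(P)=H(0.5,0.5),
        # I = sum p_ij log(p_ij/(p_i p_j))
        def h(*p):
            p = np.array(p)
            return -(p * np.log(p)).sum()
        ht = h(0.75, 0.25)
        hp = h(0.5, 0.5)
        mi = (0.5 * np.log(0.5 / (0.75 * 0.5))
              + 0.25 * np.log(0.25 / (0.75 * 0.5))
              + 0.25 * np.log(0.25 / (0.25 * 0.5)))
        assert nmi(truth, pred) == pytest.approx(mi / ((ht + hp) / 2))


def _stack_with_mz(mz, images):
    return IonImageStack(mz=np.asarray(mz), images=np.asarray(images, np.float32))


class TestIsotopeDetection:
    def test_rule_application(self):
        rng = np.random.default_rng(1)
        img = rng.random((4, 4))
        stack = _stack_with_mz(
            [500.0, 501.005],
            np.stack([img, img]),
        )
        pairs = detect_isotope_pairs(stack)
        assert len(pairs) == 1
        i, j, dm, p = pairs.pairs[0]
        assert (i, j) == (0, 1)
        assert dm == pytest.approx(1.005)
        assert p == pytest.approx(1.0)

    def test_mass_difference_outside_tolerance(self):
        rng = np.random.default_rng(1)
        img = rng.random((4, 4))
        stack = _stack_with_mz([500.0, 501.020], np.stack([img, img]))
        assert len(detect_isotope_pairs(stack)) == 0

    def test_low_correlation_rejected(self):
        rng = np.random.default_rng(2)
        stack = _stack_with_mz(
            [500.0, 501.003],
            np.stack([rng.random((6, 6)), rng.random((6, 6))]),
        )
        assert len(detect_isotope_pairs(stack)) == 0

    def test_constant_image_never_pairs(self):
        stack = _stack_with_mz(
            [500.0, 501.003],
            np.stack([np.full((4, 4), 2.0), np.full((4, 4), 3.0)]),
        )
        assert len(detect_isotope_pairs(stack)) == 0

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(3)
        n = 10
        base = rng.random((4, 4))
        images = np.stack([
            base + 0.05 * rng.random((4, 4)) if i % 2 else rng.random((4, 4))
            for i in range(n)
        ])
        mz = np.sort(rng.uniform(100, 110, n))
        stack = _stack_with_mz(mz, images)
        got = {(i, j) for i, j, _, _ in detect_isotope_pairs(stack).pairs}
        expected = set()
        for i in range(n):
            for j in range(i + 1, n):
                if abs(mz[j] - mz[i] - 1.003) < 0.01:
                    p = np.corrcoef(images[i].ravel(), images[j].ravel())[0, 1]
                    if p > 0.7:
                        expected.add((i, j))
        assert got == expected


class TestIsotopeRatios:
    def _pairs(self, idx_pairs):
        return IsotopePairSet(
            pairs=[(i, j, 1.003, 0.9) for i, j in idx_pairs]
        )

    def test_all_one_cluster(self):
        pairs = self._pairs([(0, 1), (2, 3)])
        labels = [0, 0, 0, 0]
        assert isotope_ratio(pairs, labels) == 1.0
        assert relative_isotope_ratio(pairs, labels) == pytest.approx(1.0)

    def test_counting(self):
        pairs = self._pairs([(0, 1), (2, 3), (4, 5)])
        labels = [0, 0, 1, 1, 0, 1]
        assert isotope_ratio(pairs, labels) == pytest.approx(2 / 3)

    def test_relabeling_invariance(self):
        pairs = self._pairs([(0, 1), (2, 3), (4, 5)])
        labels = np.array([0, 0, 1, 1, 0, 1])
        perm = np.array([2, 0, 1])
        assert isotope_ratio(pairs, labels) == isotope_ratio(pairs, perm[labels])

    def test_empty_pairs_undefined(self):
        with pytest.raises(UndefinedMetricError):
            isotope_ratio(IsotopePairSet(pairs=[]), [0, 1])

    def test_rir_balanced_closed_form(self):
        """All pairs co-clustered, balanced k=2, n=100: RIR = 1/(2*50*49/(100*99))."""
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1], 50)
        idx = [(i, j) for i, j in rng.integers(0, 50, (30, 2)) if i != j]
        pairs = self._pairs([(min(i, j), max(i, j)) for i, j in idx])
        expected = 1.0 / (2 * (50 * 49) / (100 * 99))
        assert relative_isotope_ratio(pairs, labels) == pytest.approx(expected)

    def test_analytic_vs_permutation(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 4, 100)
        idx = set()
        while len(idx) < 40:
            i, j = rng.integers(0, 100, 2)
            if i != j:
                idx.add((min(i, j), max(i, j)))
        pairs = self._pairs(sorted(idx))
        a = relative_isotope_ratio(pairs, labels, mode="analytic")
        p = relative_isotope_ratio(pairs, labels, mode="permutation",
                                   n_perm=20000, seed=0)
        assert a == pytest.approx(p, rel=0.02)

    def test_rir_of_random_labels_near_one(self):
        rng = np.random.default_rng(9)
        idx = {(int(min(i, j)), int(max(i, j)))
               for i, j in rng.integers(0, 200, (60, 2)) if i != j}
        pairs = self._pairs(sorted(idx))
        rirs = []
        for _ in range(50):
            labels = rng.permutation(np.repeat(np.arange(4), 50))
            rirs.append(relative_isotope_ratio(pairs, labels))
        assert 0.9 <= np.mean(rirs) <= 1.1

    def test_singletons_undefined(self):
        pairs = self._pairs([(0, 1)])
        with pytest.raises(UndefinedMetricError):
            relative_isotope_ratio(pairs, [0, 1, 2, 3])


class TestBaselines:
    def test_noiseless_separable_limit(self):
        from mzclust.data_model import normalize_stack
        from mzclust.simulate import SimulationConfig, simulate_dataset

        ls = simulate_dataset(SimulationConfig(
            images_per_cluster=8, noise_sd=0.0, hotspot_fraction=0.0,
            seed=0))
        st = normalize_stack(ls.stack)
        km = kmeans_baseline(st, 7, seed=0)
        assert clustering_accuracy(ls.truth, km) == 1.0
        gm = gmm_baseline(st, 7, seed=0)
        assert clustering_accuracy(ls.truth, gm) == 1.0

    def test_seeded_reproducibility(self, tiny_labeled_sim):
        from mzclust.data_model import normalize_stack

        st = normalize_stack(tiny_labeled_sim.stack)
        a = kmeans_baseline(st, 7, seed=5)
        b = kmeans_baseline(st, 7, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_k_exceeding_n_rejected(self, small_stack):
        with pytest.raises(ValueError):
            kmeans_baseline(small_stack, 10)
        with pytest.raises(ValueError):
            gmm_baseline(small_stack, 10)
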