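"""Self-paced schedule, pairwise loss, and small end-to-end training runs."""

import numpy as np
import pytest

from mzclust.data_model import normalize_stack
from mzclust.metrics import clustering_accuracy
from mzclust.pseudolabel import UNLABELED, similarity_matrix
from mzclust.simulate import SimulationConfig, simulate_dataset
from mzclust.trainer import (
    SelfPacedSchedule,
    TrainConfig,
    pairwise_loss,
    total_loss,
    train,
    update_schedule,
    _pairwise_grad,
)


def _random_similarity(n, seed):
    rng = np.random.default_rng(seed)
    return similarity_matrix(rng.dirichlet(np.ones(5), size=n))


class TestPairwiseLoss:
    def test_all_unlabeled_zero(self):
        A = np.full((4, 4), UNLABELED, dtype=np.int8)
        np.fill_diagonal(A, 1)
        assert pairwise_loss(A, np.eye(4)) == 0.0

    def test_perfect_classification_limits(self):
        A = np.array([[1, 1], [1, 1]], dtype=np.int8)
        S = np.ones((2, 2))
        assert pairwise_loss(A, S) == pytest.approx(0.0, abs=1e-5)
        A = np.array([[1, 0], [0, 1]], dtype=np.int8)
        S = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert pairwise_loss(A, S) == pytest.approx(0.0, abs=1e-5)

    def test_half_similarity_positive_pair(self):
        A = np.array([[1, 1], [1, 1]], dtype=np.int8)
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert pairwise_loss(A, S) == pytest.approx(np.log(2), abs=1e-6)

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(0)
        n = 8
        S = _random_similarity(n, 1)
        A = rng.choice(np.array([1, 0, UNLABELED], dtype=np.int8), size=(n, n))
        A = np.triu(A) + np.triu(A, 1).T
        np.fill_diagonal(A, 1)
        expected = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                if A[i, j] == UNLABELED:
                    continue
                s = min(max(S[i, j], 1e-7), 1 - 1e-7)
                expected += -A[i, j] * np.log(s) - (1 - A[i, j]) * np.log(1 - s)
        assert pairwise_loss(A, S) == pytest.approx(expected, rel=1e-6)

    def test_total_loss_is_sum(self):
        assert total_loss(0.0, 0.0, 0.0) == 0.0
        assert total_loss(1.0, 0.3, 0.2) == pytest.approx(1.5)

    def test_gradient_matches_finite_differences(self):
        """Analytic dL/dY agrees with numeric differentiation of the loss."""
        rng = np.random.default_rng(2)
        Y = rng.dirichlet(np.ones(4), size=6)
        A = rng.choice(np.array([1, 0, UNLABELED], dtype=np.int8), size=(6, 6))
        A = np.triu(A) + np.triu(A, 1).T
        np.fill_diagonal(A, 1)
        loss, dY = _pairwise_grad(Y, A, "bce")
        eps = 1e-6
        for idx in [(0, 0), (2, 3), (5, 1)]:
            Yp = Y.copy()
            Yp[idx] += eps
            lp, _ = _pairwise_grad(Yp, A, "bce")
            Ym = Y.copy()
            Ym[idx] -= eps
            lm, _ = _pairwise_grad(Ym, A, "bce")
            assert (lp - lm) / (2 * eps) == pytest.approx(
                dY[idx], rel=1e-3, abs=1e-7)


class TestSchedule:
    def test_cursor_arithmetic(self):
        sched = SelfPacedSchedule(l=45.0, u=95.0, lb=0.4, ub=0.9, lam=0.5,
                                  eps=5.0)
        S = _random_similarity(40, 3)
        new = update_schedule(sched, S)
        assert new.l == pytest.approx(49.0)
        assert new.u == pytest.approx(94.0)

    def test_lambda_equals_gap(self):
        S = _random_similarity(40, 4)
        sched = SelfPacedSchedule(eps=2.0).initialize(S)
        assert sched.lam == pytest.approx(sched.ub - sched.lb)
        new = update_schedule(sched, S)
        vals = S[np.triu_indices(40, 1)]
        assert new.lb == pytest.approx(np.percentile(vals, new.l))
        assert new.ub == pytest.approx(np.percentile(vals, new.u))
        assert new.lam == pytest.approx(new.ub - new.lb)

    def test_lambda_non_increasing_on_fixed_similarities(self):
        S = _random_similarity(60, 5)
        sched = SelfPacedSchedule(eps=4.0).initialize(S)
        prev = sched.lam
        for _ in range(30):
            sched = update_schedule(sched, S)
            if sched.exhausted:
                break
            assert sched.lam <= prev + 1e-9
            prev = sched.lam
        assert sched.exhausted

    def test_exhaustion_when_cursors_cross(self):
        S = _random_similarity(30, 6)
        sched = SelfPacedSchedule(l=94.0, u=95.0, lb=0.1, ub=0.9, lam=0.8,
                                  eps=10.0)
        assert update_schedule(sched, S).exhausted


class TestTraining:
    @pytest.fixture
    def mild_sim(self, _shared=[]):
        if not _shared:
            _shared.append(simulate_dataset(SimulationConfig(
                images_per_cluster=12, noise_sd=0.3, amplitude_jitter=0.3,
                hotspot_fraction=0.0, seed=5)))
        return _shared[0]

    @pytest.fixture
    def quick_cfg(self):
        return TrainConfig(pre_epochs=60, epochs=6, iterations=5,
                           cnn_channels=(4, 4, 8, 8, 8, 8, 8),
                           ae_channels=(8, 16), lr_warmup_epochs=2)

    def test_seeded_runs_identical(self, mild_sim, quick_cfg):
        st = normalize_stack(mild_sim.stack)
        _, _, rep1 = train(st, 7, quick_cfg, seed=11)
        _, _, rep2 = train(st, 7, quick_cfg, seed=11)
        np.testing.assert_array_equal(rep1.labels, rep2.labels)
        assert rep1.epochs[-1]["L_c"] == rep2.epochs[-1]["L_c"]

    def test_report_structure_and_objective_identity(self, mild_sim, quick_cfg):
        st = normalize_stack(mild_sim.stack)
        _, _, rep = train(st, 7, quick_cfg, seed=0)
        assert rep.labels is not None and len(rep.labels) == st.n
        n_pairs = st.n * (st.n - 1) // 2
        for row in rep.epochs:
            assert row["lam"] == pytest.approx(row["ub"] - row["lb"])
            assert row["total"] == pytest.approx(
                row["L_c"] + row["lam"] + row["L_ae"])
            assert row["n_pos"] + row["n_neg"] + row["n_unlabeled"] == n_pairs

    def test_labeled_count_non_decreasing_on_fixed_snapshot(self):
        """On a fixed similarity snapshot, widening the percentile window
        never removes labels (the count of selected pairs is monotone)."""
        from mzclust.pseudolabel import threshold_labels

        S = _random_similarity(60, 8)
        sched = SelfPacedSchedule(eps=4.0).initialize(S)
        iu = np.triu_indices(60, k=1)
        prev = -1
        while True:
            A = threshold_labels(S, sched.lb, sched.ub)
            labeled = int((A[iu] != UNLABELED).sum())
            assert labeled >= prev
            prev = labeled
            sched = update_schedule(sched, S)
            if sched.exhausted:
                break

    def test_no_ae_ablation_feeds_raw_images(self, mild_sim, quick_cfg):
        import dataclasses

        st = normalize_stack(mild_sim.stack)
        cfg = dataclasses.replace(quick_cfg, use_ae=False)
        ae, _, rep = train(st, 7, cfg, seed=0)
        assert ae is None
        assert all(r["L_ae"] == 0.0 for r in rep.epochs)

    def test_k_out_of_range(self, mild_sim):
        st = normalize_stack(mild_sim.stack)
        with pytest.raises(ValueError):
            train(st, 1, TrainConfig(), seed=0)
        with pytest.raises(ValueError):
            train(st, st.n + 1, TrainConfig(), seed=0)

    def test_learns_structure_far_above_chance(self, mild_sim, quick_cfg):
        """Even a miniature run (84 images) recovers most of the cluster
        structure; chance level for 7 balanced clusters is ~0.14."""
        st = normalize_stack(mild_sim.stack)
        _, _, rep = train(st, 7, quick_cfg, seed=0)
        assert clustering_accuracy(mild_sim.truth, rep.labels) >= 0.5
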