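"""k-NN density condensation (stage 1) and hard-negative mining (stage 2)."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.special import gamma as gamma_fn

from mirduplex.sample_select import (
    SampleGroup,
    knn_density,
    knn_log_density,
    knn_radius,
    prediction_deviation,
    sample_distance,
    stage1_select,
    stage2_select,
    training_set,
)


class TestDistance:
    def test_zero_iff_equal(self):
        v = np.array([1.0, 2.0, 3.0])
        assert sample_distance(v, v) == 0.0

    def test_three_four_five(self):
        assert sample_distance(np.zeros(2), np.array([3.0, 4.0])) == 5.0

    def test_matches_naive_coordinate_sum(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            u, v = rng.normal(size=7), rng.normal(size=7)
            naive = math.sqrt(sum((a - b) ** 2 for a, b in zip(u, v)))
            assert sample_distance(u, v) == pytest.approx(naive, rel=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            sample_distance(np.zeros(2), np.zeros(3))


class TestKnnRadius:
    def test_colinear_points(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0]])
        assert knn_radius(X, 0, 2) == 2.0

    def test_duplicate_point_zero_radius(self):
        X = np.array([[5.0], [5.0], [9.0]])
        assert knn_radius(X, 0, 1) == 0.0

    def test_matches_full_sort(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 3))
        for i in range(15):
            for k in (1, 3, 7):
                d = sorted(np.linalg.norm(X[i] - X[j]) for j in range(15) if j != i)
                assert knn_radius(X, i, k) == pytest.approx(d[k - 1])

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            knn_radius(np.zeros((3, 1)), 0, 3)


class TestKnnDensity:
    def test_one_dimensional_closed_form(self):
        # for i=0, k=3 -> r=2 with g=3 neighbours inside the sphere,
        # V(1,2) = 2r = 4, L = 10 -> f = 3/(10*4) = 0.075
        X = np.array([[0.0], [1.0], [2.0], [2.0]])
        assert knn_density(X, 0, 3, total_negatives=10) == pytest.approx(0.075)

    def test_equal_g_smaller_radius_denser(self):
        X = np.array([[0.0], [0.5], [1.0], [10.0], [12.0], [14.0]])
        f_tight = knn_log_density(X, 1, 2, 6)   # neighbours at 0.5
        f_loose = knn_log_density(X, 4, 2, 6)   # neighbours at 2.0
        assert f_tight > f_loose

    def test_duplicates_have_infinite_density(self):
        X = np.array([[1.0], [1.0], [3.0]])
        assert knn_log_density(X, 0, 1, 3) == np.inf

    def test_argmax_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 4))
        m, L, k = 4, 30, 3
        direct = []
        for i in range(12):
            r = sorted(np.linalg.norm(X[i] - X[j]) for j in range(12) if j != i)[k - 1]
            g = sum(
                1 for j in range(12) if j != i and np.linalg.norm(X[i] - X[j]) <= r
            )
            volume = math.pi ** (m / 2) / gamma_fn(m / 2 + 1) * r**m
            direct.append(g / (L * volume))
        ours = [knn_log_density(X, i, k, L) for i in range(12)]
        assert int(np.argmax(direct)) == int(np.argmax(ours))
        for d, o in zip(direct, ours):
            assert math.log(d) == pytest.approx(o, rel=1e-10)


def group_from(neg, premirna_id="g", pos=None):
    neg = np.atleast_2d(np.asarray(neg, dtype=float))
    pos = np.atleast_2d(pos) if pos is not None else np.empty((0, neg.shape[1]))
    return SampleGroup(
        premirna_id=premirna_id,
        neg_X=neg,
        neg_ids=list(range(len(neg))),
        pos_X=pos,
        pos_ids=list(range(len(pos))),
    )


class TestStage1:
    def test_tight_cluster_collapses_to_one(self):
        g = group_from([[0.0], [0.05], [0.1]])
        selected = stage1_select([g], k=2)["g"]
        assert len(selected) == 1

    def test_two_separated_clusters_keep_one_each(self):
        g = group_from([[0.0], [0.1], [0.2], [100.0], [100.1], [100.2]])
        selected = stage1_select([g], k=2)["g"]
        assert len(selected) == 2

    def test_hand_simulated_trace(self):
        # {0, 0.1, 0.2, 5, 5.1, 5.2}, k=2: densities peak at the middle of
        # each cluster; selecting 0.1 deletes its whole cluster (r=0.1),
        # then 5.1 deletes the other -> exactly indices [1, 4]
        g = group_from([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2]])
        assert stage1_select([g], k=2)["g"] == [1, 4]

    def test_small_group_kept_whole(self):
        g = group_from([[0.0], [1.0], [2.0]])
        assert stage1_select([g], k=11)["g"] == [0, 1, 2]

    def test_coverage_invariant(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 1, (30, 5)), rng.normal(8, 0.5, (20, 5))])
        g = group_from(X)
        selected = stage1_select([g], k=5)["g"]
        dist = cdist(X, X)
        for d in range(len(X)):
            if d in selected:
                continue
            covered = any(
                dist[d, s] <= knn_radius(X, s, 5) for s in selected
            )
            assert covered, f"sample {d} not covered by any selected hypersphere"

    def test_output_size_weakly_decreases_with_k(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 3))
        sizes = [
            len(stage1_select([group_from(X)], k=k)["g"]) for k in (2, 5, 11, 20)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestPredictionDeviation:
    def test_positive_when_negative_outranks(self):
        assert prediction_deviation(0.8, [0.5, 0.1]) == pytest.approx(0.3)

    def test_negative_when_positive_wins(self):
        assert prediction_deviation(0.2, [0.5]) == pytest.approx(-0.3)

    def test_argmax_matches_enumeration(self):
        rng = np.random.default_rng(10)
        pos = rng.normal(size=4)
        negs = rng.normal(size=25)
        sigmas = [prediction_deviation(s, pos) for s in negs]
        assert int(np.argmax(sigmas)) == int(np.argmax(negs))


class _NearestPositiveTrainer:
    """Deterministic stand-in trainer: score = -distance to nearest positive."""

    def __init__(self):
        self.calls = 0

    def __call__(self, X, z):
        self.calls += 1
        pos = X[z == 1]

        class Model:
            def decision_function(self_inner, Q):
                return -cdist(np.atleast_2d(Q), pos).min(axis=1)

        return Model()


def reference_stage2(groups, stage1, trainer, max_iter):
    """Slow literal re-implementation of the mining loop used as the oracle."""
    selected = {g.premirna_id: set(stage1[g.premirna_id]) for g in groups}
    done = {g.premirna_id: False for g in groups}
    added_ids = []
    for _ in range(max_iter):
        xs, zs = [], []
        for g in groups:
            xs += [g.pos_X, g.neg_X[sorted(selected[g.premirna_id])]]
            zs += [np.ones(len(g.pos_ids)), -np.ones(len(selected[g.premirna_id]))]
        model = trainer(np.vstack(xs), np.concatenate(zs))
        progressed = False
        for g in groups:
            if done[g.premirna_id]:
                continue
            ps = model.decision_function(g.pos_X)
            ns = model.decision_function(g.neg_X)
            if ps.max() >= ns.max():
                done[g.premirna_id] = True
                continue
            if len(selected[g.premirna_id]) == len(g.neg_ids):
                done[g.premirna_id] = True
                continue
            sigma = ns - ps.max()
            for j in np.argsort(-sigma, kind="stable"):
                if sigma[j] <= 0:
                    break
                if int(j) not in selected[g.premirna_id]:
                    selected[g.premirna_id].add(int(j))
                    added_ids.append((g.premirna_id, g.neg_ids[int(j)]))
                    progressed = True
                    break
        if all(done.values()) or not progressed:
            break
    return selected, added_ids


class TestStage2:
    def make_groups(self, seed=0, n_groups=6):
        rng = np.random.default_rng(seed)
        groups = []
        for i in range(n_groups):
            center = rng.normal(size=3) * 4
            pos = center + rng.normal(0, 0.2, (1, 3))
            neg = np.vstack(
                [center + rng.normal(0, 2.0, (15, 3)), pos + rng.normal(0, 0.05, (2, 3))]
            )
            groups.append(
                SampleGroup(f"g{i}", neg, list(range(len(neg))), pos, [0])
            )
        return groups

    def test_immediate_termination_when_already_correct(self):
        pos = np.array([[0.0, 0.0]])
        neg = np.array([[5.0, 5.0], [6.0, 6.0]])
        g = SampleGroup("g", neg, [0, 1], pos, [0])
        trainer = _NearestPositiveTrainer()
        state, _ = stage2_select([g], {"g": [0]}, trainer, max_iter=10)
        assert state.iterations == 1
        assert state.selected_neg["g"] == {0}
        assert trainer.calls == 1

    def test_exhausted_group_flagged_terminated(self):
        # negatives sit exactly on the positive: always outrank or tie
        pos = np.array([[0.0]])
        neg = np.array([[0.0], [0.0]])
        g = SampleGroup("g", neg, [0, 1], pos, [0])
        state, _ = stage2_select([g], {"g": []}, _NearestPositiveTrainer(), max_iter=10)
        assert state.terminated["g"]

    def test_matches_slow_reference_run(self):
        groups = self.make_groups(seed=12)
        stage1 = stage1_select(groups, k=3)
        state, _ = stage2_select(groups, stage1, _NearestPositiveTrainer(), max_iter=20)
        ref_selected, ref_added = reference_stage2(
            groups, stage1, _NearestPositiveTrainer(), max_iter=20
        )
        assert state.selected_neg == ref_selected
        ours_added = [(a["group"], a["candidate_id"]) for a in state.audit]
        assert ours_added == ref_added

    def test_training_set_grows_monotonically(self):
        groups = self.make_groups(seed=13)
        stage1 = stage1_select(groups, k=3)
        state, _ = stage2_select(groups, stage1, _NearestPositiveTrainer(), max_iter=20)
        n_pos = sum(len(g.pos_ids) for g in groups)
        n_initial = sum(len(v) for v in stage1.values())
        X, z = training_set(groups, state)
        assert len(z) == n_pos + n_initial + len(state.audit)
        assert (z == 1).sum() == n_pos
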