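"""RSA: RDM constructors, Spearman comparison, NNLS reweighting."""

import numpy as np
import pytest

from stslens import (
    RDM,
    ValidationError,
    feature_rdm,
    ground_truth_rdm,
    layerwise_reweight,
    nnls_reweight,
    nnls_solve,
    rdm_spearman,
    representation_rdm,
)


def _ids(n):
    return [f"i{k}" for k in range(n)]


class TestRDMConstructors:
    def test_ground_truth_two_items(self):
        r = ground_truth_rdm(_ids(2), [0.0, 5.0])
        np.testing.assert_allclose(r.matrix, [[0, 5], [5, 0]])

    def test_ground_truth_hand_offdiagonals(self):
        r = ground_truth_rdm(_ids(3), [0.0, 2.5, 5.0])
        assert (r.matrix[0, 1], r.matrix[0, 2], r.matrix[1, 2]) == (2.5, 5.0, 2.5)

    def test_equal_scores_zero_matrix(self):
        r = ground_truth_rdm(_ids(4), [3.0] * 4)
        assert not r.matrix.any()

    def test_full_test_set_shape(self):
        r = ground_truth_rdm(_ids(412), np.linspace(0, 5, 412))
        assert r.matrix.shape == (412, 412)

    def test_representation_rdm_cosine_cases(self):
        v = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        r = representation_rdm(_ids(3), v, "cosine")
        assert r.matrix[0, 1] == pytest.approx(1.0)
        assert r.matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_representation_rdm_scalar_absdiff(self):
        r = representation_rdm(_ids(2), np.array([0.1, 0.4]), "abs_diff")
        assert r.matrix[0, 1] == pytest.approx(0.3)

    def test_zero_norm_vector_names_item(self):
        v = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValidationError, match="i1"):
            representation_rdm(_ids(2), v, "cosine")

    def test_feature_rdm_hand_cases(self):
        r = feature_rdm(_ids(3), [10.0, 14.0, 12.0], "length")
        assert (r.matrix[0, 1], r.matrix[0, 2], r.matrix[1, 2]) == (4.0, 2.0, 2.0)
        flat = feature_rdm(_ids(3), [2.0, 2.0, 2.0], "const")
        assert flat.degenerate and not flat.matrix.any()

    def test_random_inputs_yield_valid_rdms(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 12))
            which = rng.integers(0, 3)
            if which == 0:
                r = ground_truth_rdm(_ids(n), rng.uniform(0, 5, n))
            elif which == 1:
                r = representation_rdm(_ids(n), rng.normal(size=(n, 4)), "cosine")
            else:
                r = feature_rdm(_ids(n), rng.normal(size=n), "f")
            m = r.matrix
            assert np.allclose(m, m.T)
            assert np.allclose(np.diag(m), 0)
            assert (m >= 0).all()

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValidationError):
            RDM(_ids(2), np.array([[0.0, 1.0], [2.0, 0.0]]), "asym")
        with pytest.raises(ValidationError):
            RDM(_ids(2), np.array([[1.0, 0.0], [0.0, 0.0]]), "diag")
        with pytest.raises(ValidationError):
            RDM(_ids(2), np.array([[0.0, -1.0], [-1.0, 0.0]]), "neg")


class TestRDMSpearman:
    def test_self_correlation_and_scale_invariance(self, rng):
        r = representation_rdm(_ids(8), rng.normal(size=(8, 3)), "cosine")
        assert rdm_spearman(r, r) == pytest.approx(1.0)
        scaled = RDM(r.item_ids, 2.5 * r.matrix, "scaled")
        assert rdm_spearman(r, scaled) == pytest.approx(1.0)

    def test_invariant_under_strictly_increasing_transforms(self, rng):
        a = representation_rdm(_ids(10), rng.normal(size=(10, 4)), "cosine")
        b = ground_truth_rdm(_ids(10), rng.uniform(0, 5, 10))
        base = rdm_spearman(a, b)
        for f in (np.sqrt, np.tanh, lambda x: x / (1 + x), lambda x: x**1.7):
            ta = RDM(a.item_ids, f(a.matrix), "t")
            assert rdm_spearman(ta, b) == pytest.approx(base, abs=1e-12)

    def test_hand_worked_four_item_case(self):
        # triangles [1..6] vs [2,1,4,3,6,5]: sum d^2 = 6,
        # rho = 1 - 6*6/(6*35) = 29/35
        def from_tri(tri):
            m = np.zeros((4, 4))
            m[np.triu_indices(4, 1)] = tri
            return RDM(_ids(4), m + m.T, "hand")

        a = from_tri([1, 2, 3, 4, 5, 6])
        b = from_tri([2, 1, 4, 3, 6, 5])
        assert rdm_spearman(a, b) == pytest.approx(29 / 35, abs=1e-12)

    def test_constant_triangle_reports_missing(self):
        flat = ground_truth_rdm(_ids(3), [1.0, 1.0, 1.0])
        other = ground_truth_rdm(_ids(3), [0.0, 1.0, 2.0])
        assert np.isnan(rdm_spearman(flat, other))

    def test_mismatched_items_rejected(self, rng):
        a = representation_rdm(_ids(4), rng.normal(size=(4, 2)), "cosine")
        b = representation_rdm(["x0", "x1", "x2", "x3"], rng.normal(size=(4, 2)), "cosine")
        with pytest.raises(ValidationError):
            rdm_spearman(a, b)


def _random_rdm(rng, n, dim=5, source="c"):
    return representation_rdm(_ids(n), rng.normal(size=(n, dim)), "cosine", source)


class TestNNLS:
    def test_exact_member_recovery(self, rng):
        c1 = _random_rdm(rng, 20, source="c1")
        c2 = _random_rdm(rng, 20, source="c2")
        target = RDM(c1.item_ids, c1.matrix.copy(), "target")
        fit = nnls_reweight([c1, c2], target, folds=5, seed=0)
        np.testing.assert_allclose(fit.normalized_weights, [1.0, 0.0], atol=1e-8)
        assert fit.cv_spearman == pytest.approx(1.0)

    def test_opposed_candidate_forced_to_zero_weight(self, rng):
        # non-negativity can only zero a candidate that is anti-aligned in
        # the least-squares sense; build one supported exactly where the
        # target vanishes, so any positive weight increases the residual
        n = 12
        tri = np.triu_indices(n, k=1)
        mask = rng.random(tri[0].size) < 0.5
        t_mat = np.zeros((n, n))
        t_mat[tri] = np.where(mask, rng.uniform(1, 2, mask.size), 0.0)
        c_mat = np.zeros((n, n))
        c_mat[tri] = np.where(mask, 0.0, rng.uniform(1, 2, mask.size))
        target = RDM(_ids(n), t_mat + t_mat.T, "t")
        opposed = RDM(_ids(n), c_mat + c_mat.T, "anti")
        fit = nnls_reweight([opposed], target, folds=4, seed=0)
        assert fit.degenerate
        np.testing.assert_allclose(fit.raw_weights, 0.0, atol=1e-10)

    def test_convex_combination_recovered_against_grid_oracle(self, rng):
        c1, c2 = _random_rdm(rng, 12, source="c1"), _random_rdm(rng, 12, source="c2")
        target = RDM(c1.item_ids, 0.3 * c1.matrix + 0.7 * c2.matrix, "t")
        fit = nnls_reweight([c1, c2], target, folds=6, seed=0)
        np.testing.assert_allclose(fit.normalized_weights, [0.3, 0.7], atol=0.02)

        A = np.column_stack([c1.triangle(), c2.triangle()])
        b = target.triangle()
        _, resid = nnls_solve(A, b)
        grid_best = np.inf
        for w1 in np.arange(0.0, 1.0001, 0.01):
            d = A @ np.array([w1, 1 - w1])
            dd = d @ d
            alpha = max((d @ b) / dd, 0.0) if dd > 0 else 0.0
            grid_best = min(grid_best, np.linalg.norm(alpha * d - b))
        assert abs(resid - grid_best) <= 1e-6

    def test_solver_never_worse_than_grid_on_random_problems(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 9))
            cands = [_random_rdm(rng, n, source=f"c{j}") for j in range(3)]
            target = _random_rdm(rng, n, source="t")
            A = np.column_stack([c.triangle() for c in cands])
            b = target.triangle()
            _, resid = nnls_solve(A, b)
            grid_best = np.inf
            steps = np.arange(0.0, 1.0001, 0.01)
            for w1 in steps:
                for w2 in np.arange(0.0, 1.0001 - w1, 0.01):
                    w = np.array([w1, w2, 1 - w1 - w2])
                    d = A @ w
                    dd = d @ d
                    alpha = max((d @ b) / dd, 0.0) if dd > 0 else 0.0
                    grid_best = min(grid_best, np.linalg.norm(alpha * d - b))
            assert resid <= grid_best + 1e-6

    def test_all_zero_candidates_rejected(self):
        z = RDM(_ids(4), np.zeros((4, 4)), "z")
        t = ground_truth_rdm(_ids(4), [0, 1, 2, 3])
        with pytest.raises(ValidationError):
            nnls_reweight([z], t, folds=2, seed=0)

    def test_weights_nonnegative_and_normalized(self, rng):
        cands = [_random_rdm(rng, 25, source=f"c{j}") for j in range(4)]
        target = ground_truth_rdm(_ids(25), rng.uniform(0, 5, 25))
        fit = nnls_reweight(cands, target, folds=5, seed=3)
        assert (fit.raw_weights >= 0).all()
        if not fit.degenerate:
            assert fit.normalized_weights.sum() == pytest.approx(1.0)


class TestLayerwise:
    def test_each_layer_normalized_and_labelled(self, rng):
        target = ground_truth_rdm(_ids(20), rng.uniform(0, 5, 20))
        layer_cands = {
            layer: [_random_rdm(rng, 20, source=f"L{layer}-c{j}") for j in range(3)]
            for layer in (2, 4, 6)
        }
        table, fits = layerwise_reweight(layer_cands, target, folds=5, seed=0)
        assert sorted(table.layer.unique()) == [2, 4, 6]
        for layer, fit in fits.items():
            if not fit.degenerate:
                sums = table[table.layer == layer].normalized_weight.sum()
                assert sums == pytest.approx(1.0)

    def test_planted_cls_layer_dominates_weights(self, small_corpus):
        from stslens import ModelSpec, Planting, build_all, generate_activations
        from stslens.pipeline import _representation_rdms

        spec = ModelSpec("m", 4, 16, "cls_first")
        acts = generate_activations(
            small_corpus.test, spec, [Planting(3, "cls", 4.0)], seed=8
        )
        table = build_all(acts, [1, 2, 3, 4])
        ids = table.pair_ids
        gold = {p.pair_id: p.score for p in small_corpus.test}
        target = ground_truth_rdm(ids, [gold[i] for i in ids])
        rep_rdms = _representation_rdms(table, ids)
        by_layer = {
            L: [rep_rdms[(rep, L)] for rep in table.rep_names] for L in (1, 2, 3, 4)
        }
        out, fits = layerwise_reweight(by_layer, target, folds=5, seed=0)
        planted = out[(out.layer == 3) & (out.candidate == "representation(m,cls,L3)")]
        assert planted.normalized_weight.iloc[0] >= 0.5
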