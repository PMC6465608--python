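import numpy as np
import pytest

from tls2d.lsd import soft_threshold
from tls2d.structured import (
    ProxState,
    WeightMap,
    binarize_sparse,
    build_groups,
    omega_norm,
    prox_structured,
    singleton_groups,
)

from oracles import prox_oracle_qp


class TestBuildGroups:
    def test_single_group_3x3(self):
        g = build_groups(3, 3)
        assert g.n_groups == 1
        assert set(g.indices[0]) == set(range(9))

    def test_neighbor_overlap_is_six_pixels(self):
        g = build_groups(4, 3)
        assert g.n_groups == 2
        shared = set(g.indices[0]) & set(g.indices[1])
        assert len(shared) == 6

    def test_count_formula(self):
        assert build_groups(5, 5).n_groups == 9
        assert build_groups(10, 7).n_groups == 8 * 5

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            build_groups(2, 5)

    def test_colors_partition_into_disjoint_groups(self):
        g = build_groups(9, 8)
        seen = np.zeros(g.n_groups, dtype=int)
        for rows in g.colors:
            seen[rows] += 1
            pix = g.indices[rows].ravel()
            assert len(pix) == len(set(pix))  # no collisions within a color
        assert np.all(seen == 1)


class TestOmegaNorm:
    def test_zero_matrix(self):
        g = build_groups(3, 3)
        assert omega_norm(np.zeros((9, 2)), g) == 0.0

    def test_single_group_takes_max_abs(self):
        g = build_groups(3, 3)
        S = np.zeros(9)
        S[4] = 4.0
        assert omega_norm(S, g) == 4.0
        S[4] = -4.0
        assert omega_norm(S, g) == 4.0

    def test_two_group_hand_sum(self):
        # 4x3 image: group 1 = cols 0..2, group 2 = cols 1..3; put the
        # maxima in the non-shared pixels so each group has its own max
        g = build_groups(4, 3)
        img = np.zeros((3, 4))
        img[1, 0] = -2.0  # only in group 1
        img[1, 3] = 5.0  # only in group 2
        assert omega_norm(img.ravel(), g) == 7.0

    def test_upper_bounds_max_abs(self):
        rng = np.random.default_rng(0)
        g = build_groups(6, 5)
        for _ in range(10):
            S = rng.normal(size=(30, 2))
            assert omega_norm(S, g) >= np.abs(S).max() - 1e-12

    def test_shape_mismatch_rejected(self):
        g = build_groups(4, 4)
        with pytest.raises(ValueError):
            omega_norm(np.zeros((9, 1)), g)


class TestWeightMap:
    def test_constant_map(self):
        g = build_groups(4, 4)
        W = WeightMap.constant(0.3).group_weights(g, 5)
        assert W.shape == (g.n_groups, 5)
        assert np.all(W == 0.3)

    def test_adaptive_from_probability(self):
        g = build_groups(3, 3)
        P = np.zeros((9, 1))
        P[4, 0] = 1.0
        W = WeightMap.from_probability(0.9, P).group_weights(g, 1)
        # one pixel fully "tumor": group weight is the mean pixel weight
        assert W[0, 0] == pytest.approx(0.9 * 8 / 9)

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            WeightMap.from_probability(1.0, np.full((4, 1), 1.5))

    def test_constant_array_equals_scalar_exactly(self):
        g = build_groups(5, 5)
        W1 = WeightMap.constant(0.37).group_weights(g, 3)
        W2 = WeightMap(values=np.full((25, 3), 0.37)).group_weights(g, 3)
        assert np.array_equal(W1, W2)


class TestProxStructured:
    def test_zero_input(self):
        g = build_groups(4, 4)
        assert np.all(prox_structured(np.zeros((16, 2)), g, 1.0, mu=1.0) == 0)

    def test_single_group_small_input_collapses_to_zero(self):
        # Moreau: with one group, prox(h) = h - proj_{l1 ball w/mu}(h),
        # so ||h||_1 <= w/mu gives exactly 0
        g = build_groups(3, 3)
        rng = np.random.default_rng(1)
        h = rng.normal(size=9)
        h *= 0.9 / (np.abs(h).sum())  # l1 norm 0.9 < w/mu = 1
        out = prox_structured(h, g, 1.0, mu=1.0, tol=1e-12, max_passes=50000)
        assert np.abs(out).max() < 1e-9

    def test_single_group_moreau_identity(self):
        g = build_groups(3, 3)
        rng = np.random.default_rng(2)
        h = rng.normal(size=9) * 3
        w_g, mu = 1.7, 0.8
        out = prox_structured(h, g, w_g, mu=mu, tol=1e-10, max_passes=10000)
        # project h onto the l1 ball of radius w_g/mu by bisection on the
        # shrinkage level, then apply Moreau's decomposition
        lo, hi = 0.0, np.abs(h).max()
        for _ in range(200):
            mid = (lo + hi) / 2
            if np.maximum(np.abs(h) - mid, 0).sum() > w_g / mu:
                lo = mid
            else:
                hi = mid
        theta = (lo + hi) / 2
        proj = np.sign(h) * np.maximum(np.abs(h) - theta, 0.0)
        assert np.abs(out - (h - proj)).max() < 1e-6

    def test_singleton_groups_reduce_to_soft_threshold(self):
        rng = np.random.default_rng(3)
        g = singleton_groups(5, 4)
        h = rng.normal(size=20)
        out = prox_structured(h, g, 0.4, mu=2.0)
        assert np.allclose(out, soft_threshold(h, 0.2), atol=1e-12)

    def test_matches_qp_oracle(self):
        rng = np.random.default_rng(3)
        g = build_groups(6, 6)
        for _ in range(5):
            h = rng.normal(size=36)
            mine = prox_structured(h, g, 1.0, mu=1.0)
            ref = prox_oracle_qp(h, g, np.ones(g.n_groups), 1.0)
            assert np.abs(mine - ref).max() < 1e-4

    def test_nonexpansive(self):
        rng = np.random.default_rng(4)
        g = build_groups(5, 5)
        for _ in range(5):
            a = rng.normal(size=25)
            b = rng.normal(size=25)
            pa = prox_structured(a, g, 1.0, mu=1.0)
            pb = prox_structured(b, g, 1.0, mu=1.0)
            assert np.linalg.norm(pa - pb) <= np.linalg.norm(a - b) + 1e-6

    def test_zero_weights_return_input(self):
        rng = np.random.default_rng(5)
        g = build_groups(5, 5)
        h = rng.normal(size=25)
        out = prox_structured(h, g, 0.0, mu=1.0)
        assert np.allclose(out, h, atol=1e-12)

    def test_output_omega_never_exceeds_input(self):
        rng = np.random.default_rng(6)
        g = build_groups(6, 6)
        for _ in range(5):
            h = rng.normal(size=36)
            out = prox_structured(h, g, 0.7, mu=1.0)
            assert omega_norm(out, g) <= omega_norm(h, g) + 1e-9

    def test_warm_start_state_reaches_same_answer(self):
        rng = np.random.default_rng(7)
        g = build_groups(6, 6)
        H = rng.normal(size=(36, 3))
        cold = prox_structured(H, g, 0.5, mu=2.0, tol=1e-9, max_passes=10000)
        state = ProxState.empty(g, 3)
        prox_structured(H, g, 0.5, mu=1.0, state=state)
        warm = prox_structured(
            H, g, 0.5, mu=2.0, state=state, tol=1e-9, max_passes=10000
        )
        assert np.abs(cold - warm).max() < 1e-6

    def test_nonconvergence_names_column(self):
        rng = np.random.default_rng(8)
        g = build_groups(6, 6)
        H = rng.normal(size=(36, 2))
        with pytest.raises(RuntimeError, match="column"):
            prox_structured(H, g, 1.0, mu=1.0, max_passes=1, tol=1e-14)


class TestBinarizeSparse:
    def test_all_zero_gives_empty_mask(self):
        assert not binarize_sparse(np.zeros((8, 8))).any()

    def test_bimodal_separation(self):
        S = np.zeros((20, 20))
        S.ravel()[:100] = 0.5
        mask = binarize_sparse(S)
        assert mask.sum() == 100
        assert np.all(mask.ravel()[:100])

    def test_uniform_tiny_noise_killed_by_floor(self):
        rng = np.random.default_rng(0)
        S = rng.uniform(-0.01, 0.01, size=(16, 16))
        assert not binarize_sparse(S).any()

    def test_speckle_plus_lesion(self):
        rng = np.random.default_rng(1)
        S = rng.uniform(-0.02, 0.02, size=(20, 20))
        S[5:10, 5:10] = 0.4
        mask = binarize_sparse(S)
        assert mask[5:10, 5:10].all()
        assert mask.sum() == 25
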