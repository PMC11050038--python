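"""Stage I: winner search, neighbourhood, CP-ANN training, neuron extraction,
descriptor reduction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cpbpe as cb
from cpbpe.cpann import neighborhood_grid, update_step


class TestFindWinner:
    def test_exact_match_has_zero_distance(self):
        rng = np.random.default_rng(0)
        grid = rng.uniform(0, 1, (3, 4, 5))
        row, col, dist = cb.find_winner(grid, grid[1, 2])
        assert (row, col) == (1, 2)
        assert dist == 0.0

    def test_tie_breaks_to_smallest_row_major_index(self):
        grid = np.random.default_rng(1).uniform(0, 1, (2, 3, 4))
        grid[1, 2] = grid[0, 0]  # flat indices 0 and 5 identical
        row, col, _ = cb.find_winner(grid, grid[0, 0])
        assert (row, col) == (0, 0)

    def test_dimension_mismatch(self):
        grid = np.zeros((2, 2, 3))
        with pytest.raises(cb.ConfigurationError):
            cb.find_winner(grid, np.zeros(4))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.uniform(0, 1, (3, 3, 4))
        x = rng.uniform(-0.5, 1.5, 4)
        best, best_d = None, np.inf
        for r in range(3):
            for c in range(3):
                d = float(np.sqrt(((grid[r, c] - x) ** 2).sum()))
                if d < best_d:
                    best, best_d = (r, c), d
        row, col, dist = cb.find_winner(grid, x)
        assert (row, col) == best
        assert dist == pytest.approx(best_d, abs=1e-12)


class TestNeighborhood:
    def test_winner_always_one(self):
        for radius in (0.0, 1.0, 3.7):
            assert cb.neighborhood_factor((1, 1), (1, 1), radius, 5, 5) == 1.0

    def test_radius_zero_triangular_kills_neighbours(self):
        assert cb.neighborhood_factor((0, 0), (0, 1), 0.0, 5, 5) == 0.0

    def test_toroidal_wraps_corners(self):
        # winner (0,0), neuron (4,4) on 5x5: modular distance is 1 each way
        dr = min(abs(0 - 4), 5 - abs(0 - 4))
        assert dr == 1
        planar = cb.neighborhood_factor((0, 0), (4, 4), 2.0, 5, 5)
        toroidal = cb.neighborhood_factor((0, 0), (4, 4), 2.0, 5, 5,
                                          topology="toroidal")
        assert planar == 0.0  # chebyshev 4 > radius band
        assert toroidal == pytest.approx(1.0 - 1.0 / 3.0)

    def test_rectangular_is_indicator(self):
        assert cb.neighborhood_factor((0, 0), (0, 2), 2.0, 5, 5,
                                      shape="rectangular") == 1.0
        assert cb.neighborhood_factor((0, 0), (0, 3), 2.0, 5, 5,
                                      shape="rectangular") == 0.0

    @given(st.floats(0, 6), st.integers(0, 4), st.integers(0, 4))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_grid_distance(self, radius, wr, wc):
        grid = neighborhood_grid((wr, wc), 5, 5, radius)
        d = np.maximum(np.abs(np.arange(5) - wr)[:, None],
                       np.abs(np.arange(5) - wc)[None, :])
        order = np.argsort(d.ravel(), kind="stable")
        factors = grid.ravel()[order]
        assert (np.diff(factors) <= 1e-12).all()


class TestTraining:
    def test_single_compound_fixed_point(self):
        ds = cb.Dataset(ids=["a"], X=np.array([[0.3, 0.7]]), T=np.array([0.4]),
                        descriptor_names=["d1", "d2"])
        params = cb.ScalingParams(x_min=np.zeros(2), x_max=np.ones(2),
                                  t_min=0.0, t_max=1.0)
        model = cb.train_cpann(ds, cb.CPANNConfig(1, 1, epochs=100, seed=0),
                               scaling=params)
        np.testing.assert_allclose(model.kohonen[0, 0], [0.3, 0.7], atol=1e-3)
        np.testing.assert_allclose(model.grossberg[0, 0], 0.4, atol=1e-3)

    def test_two_clusters_reach_cluster_means(self):
        rng = np.random.default_rng(2)
        a = 0.2 + 0.02 * rng.uniform(-1, 1, (20, 2))
        b = 0.8 + 0.02 * rng.uniform(-1, 1, (20, 2))
        X = np.vstack([a, b])
        T = np.concatenate([rng.uniform(0.18, 0.22, 20),
                            rng.uniform(0.78, 0.82, 20)])
        ds = cb.Dataset(ids=[str(i) for i in range(40)], X=X, T=T,
                        descriptor_names=["d1", "d2"])
        params = cb.ScalingParams(x_min=np.zeros(2), x_max=np.ones(2),
                                  t_min=0.0, t_max=1.0)
        model = cb.train_cpann(ds, cb.CPANNConfig(2, 1, epochs=400, seed=2),
                               scaling=params)
        values = sorted(model.grossberg.ravel())
        assert values[0] == pytest.approx(T[:20].mean(), abs=0.05)
        assert values[1] == pytest.approx(T[20:].mean(), abs=0.05)

    def test_same_seed_bit_identical(self, smooth_dataset):
        params = cb.fit_scaling(smooth_dataset)
        scaled = cb.scale(smooth_dataset, params)
        config = cb.CPANNConfig(4, 4, epochs=30, seed=9)
        m1 = cb.train_cpann(scaled, config, scaling=params)
        m2 = cb.train_cpann(scaled, config, scaling=params)
        np.testing.assert_array_equal(m1.kohonen, m2.kohonen)
        np.testing.assert_array_equal(m1.grossberg, m2.grossberg)
        np.testing.assert_array_equal(m1.train_distances, m2.train_distances)

    def test_radius_zero_update_touches_only_winner(self):
        rng = np.random.default_rng(3)
        koh = rng.uniform(0, 1, (3, 3, 2))
        gross = rng.uniform(0, 1, (3, 3))
        koh0, gross0 = koh.copy(), gross.copy()
        x = rng.uniform(0, 1, 2)
        wr, wc = update_step(koh, gross, x, 0.9, eta=0.3, radius=0.0)
        changed = np.nonzero((koh != koh0).any(axis=2) | (gross != gross0))
        assert list(zip(*changed)) == [(wr, wc)]

    def test_fixed_point_of_update_rule(self):
        # if the pattern sits exactly on a neuron and the target equals its
        # Grossberg value, a radius-0 update changes nothing
        rng = np.random.default_rng(4)
        koh = rng.uniform(0, 1, (2, 2, 3))
        gross = rng.uniform(0, 1, (2, 2))
        koh0, gross0 = koh.copy(), gross.copy()
        update_step(koh, gross, koh0[1, 0].copy(), float(gross0[1, 0]),
                    eta=0.7, radius=0.0)
        np.testing.assert_allclose(koh, koh0, atol=1e-12)
        np.testing.assert_allclose(gross, gross0, atol=1e-12)

    def test_occupancy_and_distances_recorded(self, trained_model):
        cp = trained_model.cpann
        assert cp.train_distances.shape == (120,)
        assert cp.occupancy.sum() == 120


class TestPrediction:
    def test_lookup_constant_within_a_neuron(self, trained_model):
        cp = trained_model.cpann
        rng = np.random.default_rng(6)
        base = rng.uniform(0.2, 0.8, cp.n)
        raw = cp.scaling.x_min + base * (cp.scaling.x_max - cp.scaling.x_min)
        v1, w1, _ = cb.predict_cpann(cp, raw)
        v2, w2, _ = cb.predict_cpann(cp, raw * (1 + 1e-9))
        assert w1 == w2
        assert v1 == v2

    def test_cardinality_bounded_by_neuron_count(self, trained_model):
        cp = trained_model.cpann
        rng = np.random.default_rng(7)
        X = rng.uniform(cp.scaling.x_min, cp.scaling.x_max, (2000, cp.n))
        values, _, _ = cb.predict_cpann_batch(cp, X)
        assert len(np.unique(values)) <= cp.config.k

    def test_batch_matches_scalar_path(self, trained_model):
        cp = trained_model.cpann
        rng = np.random.default_rng(8)
        X = rng.uniform(cp.scaling.x_min, cp.scaling.x_max, (20, cp.n))
        values, winners, distances = cb.predict_cpann_batch(cp, X)
        for i in range(20):
            v, (r, c), d = cb.predict_cpann(cp, X[i])
            assert values[i] == pytest.approx(v, abs=1e-12)
            assert winners[i] == r * cp.config.map_cols + c
            assert distances[i] == pytest.approx(d, abs=1e-12)


class TestExtractNeurons:
    def test_row_identity_and_count(self, trained_model):
        neurons = cb.extract_neurons(trained_model.cpann)
        assert neurons.k == 36
        j = 17
        r, c = neurons.neuron_coords[j]
        np.testing.assert_array_equal(neurons.inputs[j],
                                      trained_model.cpann.kohonen[r, c])
        assert neurons.targets[j] == trained_model.cpann.grossberg[r, c]

    def test_occupied_only_drops_empty_neurons(self, trained_model):
        neurons = cb.extract_neurons(trained_model.cpann, occupied_only=True)
        assert neurons.k == int((trained_model.cpann.occupancy > 0).sum())
        assert (neurons.occupancy > 0).all()


class TestReduceDescriptors:
    @pytest.fixture
    def redundant_dataset(self):
        rng = np.random.default_rng(9)
        base = rng.uniform(0, 1, (60, 4))
        X = np.column_stack([base, 2.0 * base[:, 0] + 0.3,   # r = 1 with col 0
                             np.full(60, 7.0)])              # constant
        return cb.Dataset(ids=[str(i) for i in range(60)], X=X,
                          T=rng.uniform(-8, 0, 60),
                          descriptor_names=[f"d{i}" for i in range(6)])

    def test_correlated_and_constant_columns_dropped(self, redundant_dataset):
        with pytest.warns(UserWarning, match="constant"):
            selected = cb.reduce_descriptors(redundant_dataset, map_rows=1,
                                             map_cols=1, seed=0)
        assert "d4" not in selected  # later member of the correlated pair
        assert "d5" not in selected  # constant
        assert set(selected) <= {"d0", "d1", "d2", "d3"}

    def test_single_neuron_selects_min_and_max_distance(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(0, 1, (40, 6))
        ds = cb.Dataset(ids=[str(i) for i in range(40)], X=X,
                        T=rng.uniform(-8, 0, 40),
                        descriptor_names=[f"d{i}" for i in range(6)])
        selected = cb.reduce_descriptors(ds, map_rows=1, map_cols=1, seed=3,
                                         epochs=50)
        assert len(selected) == 2
        # oracle: recompute distances of every descriptor to the single neuron
        params = cb.fit_scaling(ds)
        objects = cb.data.scale_matrix(ds.X, params).T
        weights = cb.train_kohonen(objects,
                                   cb.CPANNConfig(1, 1, epochs=50, seed=3))
        d = np.sqrt(((objects - weights[0, 0]) ** 2).sum(axis=1))
        expected = {ds.descriptor_names[int(np.argmin(d))],
                    ds.descriptor_names[int(np.argmax(d))]}
        assert set(selected) == expected

    def test_all_filtered_is_an_error(self):
        ds = cb.Dataset(ids=["a", "b"], X=np.array([[1.0, 2.0], [1.0, 2.0]]),
                        T=np.array([0.0, 1.0]), descriptor_names=["x", "y"])
        with pytest.warns(UserWarning, match="constant"):
            with pytest.raises(cb.ConfigurationError):
                cb.reduce_descriptors(ds, map_rows=1, map_cols=1)
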