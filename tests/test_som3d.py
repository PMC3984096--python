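"""SOM lattice geometry, schedules, training dynamics and determinism."""

from dataclasses import replace

import numpy as np
import pytest

from somroi import (
    FeatureSpace,
    SomConfig,
    find_bmu,
    lattice_distance,
    learning_rate,
    neighborhood_value,
    quantization_error,
    train,
)
from somroi.som3d import (
    PhaseSchedule,
    SomModel,
    bmu_indices,
    lattice_coordinates,
)


def _model_with(prototypes, lattice_shape=(2, 2, 2), topology="flat"):
    return SomModel(
        prototypes=np.asarray(prototypes, dtype=np.float64),
        lattice_coords=lattice_coordinates(lattice_shape),
        topology=topology,
        lattice_shape=lattice_shape,
        config=SomConfig(lattice_shape=lattice_shape, topology=topology),
    )


def _point_cloud_fs(X):
    """Wrap a raw (P, 4) array as a FeatureSpace for training tests."""
    X = np.asarray(X, dtype=np.float64)
    P = X.shape[0]
    return FeatureSpace(
        vectors=X,
        voxel_index=np.zeros((P, 3), dtype=np.int64),
        offset=np.zeros(4),
        gain=np.ones(4),
        mask=np.ones((P, 1, 1), dtype=bool),
        d_weight=1.0,
        grid_shape=(P, 1, 1),
    )


class TestLatticeDistance:
    def test_identity_and_345(self):
        model = _model_with(np.zeros((200, 4)), lattice_shape=(5, 5, 8))
        coords = model.lattice_coords
        i = int(np.flatnonzero((coords == [0, 0, 0]).all(axis=1))[0])
        j = int(np.flatnonzero((coords == [3, 4, 0]).all(axis=1))[0])
        assert lattice_distance(model, i, i) == 0.0
        assert lattice_distance(model, i, j) == 5.0

    def test_cylindrical_wraps_first_axis(self):
        model = _model_with(np.zeros((10, 4)), lattice_shape=(10, 1, 1), topology="cylindrical")
        assert lattice_distance(model, 0, 9) == 1.0
        assert lattice_distance(model, 0, 5) == 5.0
        flat = _model_with(np.zeros((10, 4)), lattice_shape=(10, 1, 1), topology="flat")
        assert lattice_distance(flat, 0, 9) == 9.0

    def test_out_of_range_raises(self):
        model = _model_with(np.zeros((8, 4)))
        with pytest.raises(IndexError):
            lattice_distance(model, 0, 8)

    def test_lattice_coords_are_row_major_mixed_radix(self):
        coords = lattice_coordinates((3, 4, 5))
        for i in range(60):
            assert tuple(coords[i]) == (i // 20, (i // 5) % 4, i % 5)


class TestBmu:
    def test_nearest_and_tie_rule(self):
        protos = np.zeros((6, 4))
        protos[5] = [1, 1, 1, 1]
        model = _model_with(protos, lattice_shape=(6, 1, 1))
        assert find_bmu(model, [0.1, 0, 0, 0]) == 0
        # exact tie between units 2 and 5: lowest index wins
        protos = np.arange(24).reshape(6, 4).astype(float)
        protos[5] = protos[2]
        model = _model_with(protos, lattice_shape=(6, 1, 1))
        assert find_bmu(model, protos[2] + 0.1) == 2

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        protos = rng.standard_normal((50, 4))
        model = _model_with(protos, lattice_shape=(50, 1, 1))
        queries = rng.standard_normal((100, 4))
        for q in queries:
            expected = min(
                range(50), key=lambda i: float(np.sum((q - protos[i]) ** 2))
            )
            assert find_bmu(model, q) == expected
        # vectorized assignment agrees with the scalar path
        np.testing.assert_array_equal(
            bmu_indices(protos, queries),
            [find_bmu(model, q) for q in queries],
        )


class TestSchedules:
    def test_neighborhood_values(self):
        assert neighborhood_value(0.0, 2.0) == 1.0
        sigma = 1.7
        half_width = sigma * np.sqrt(2 * np.log(2))
        assert np.isclose(neighborhood_value(half_width, sigma), 0.5)
        assert neighborhood_value(2.0, sigma) < neighborhood_value(1.0, sigma)
        with pytest.raises(ValueError):
            neighborhood_value(1.0, 0.0)

    def test_learning_rate_decay(self):
        assert learning_rate(0.1, 0, 100) == 0.1
        assert learning_rate(0.1, 100, 100) == pytest.approx(0.05)
        vals = [learning_rate(0.1, t, 100) for t in range(0, 301)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestTraining:
    def test_single_unit_converges_to_data_mean(self):
        rng = np.random.default_rng(5)
        X = rng.normal(loc=[4.0, -2.0, 1.0, 3.0], scale=0.2, size=(100, 4))
        config = SomConfig(
            lattice_shape=(1, 1, 1),
            phase1=PhaseSchedule(alpha0=0.1, sigma0=1.0, epochs=30, sigma_floor=1.0),
            phase2=PhaseSchedule(alpha0=0.01, sigma0=0.5, epochs=60, sigma_floor=0.5),
            seed=3,
        )
        model = train(_point_cloud_fs(X), config)
        mean = X.mean(axis=0)
        rel_err = np.linalg.norm(model.prototypes[0] - mean) / np.linalg.norm(mean)
        assert rel_err < 1e-3

    def test_identical_vectors_collapse_prototypes(self):
        X = np.tile([0.3, 0.6, 0.1, 0.9], (50, 1))
        model = train(_point_cloud_fs(X), SomConfig(lattice_shape=(2, 2, 1), seed=1))
        assert model.qe_history[-1] < 1e-6
        np.testing.assert_allclose(model.prototypes, np.tile(X[0], (4, 1)), atol=1e-4)

    def test_qe_improves_on_phantom_features(self, trained_som):
        assert trained_som.qe_history[-1] <= trained_som.qe_history[0]

    def test_prototypes_stay_in_bounding_box(self, small_feature_space, fast_som_config):
        model = train(small_feature_space, fast_som_config)
        lo = small_feature_space.vectors.min(axis=0)
        hi = small_feature_space.vectors.max(axis=0)
        # linear init lies inside the data box, so updates cannot escape it
        assert (model.prototypes >= lo - 1e-12).all()
        assert (model.prototypes <= hi + 1e-12).all()

    def test_topology_preservation_tendency(self, trained_som):
        W = trained_som.prototypes
        coords = trained_som.lattice_coords
        adj, rand = [], []
        rng = np.random.default_rng(0)
        m = len(W)
        for i in range(m):
            for j in range(i + 1, m):
                d_lat = np.abs(coords[i] - coords[j]).sum()
                if d_lat == 1:
                    adj.append(np.linalg.norm(W[i] - W[j]))
        for _ in range(500):
            i, j = rng.integers(0, m, 2)
            if i != j:
                rand.append(np.linalg.norm(W[i] - W[j]))
        assert np.mean(adj) < np.mean(rand)

    def test_bit_identical_from_seed(self, small_feature_space, fast_som_config):
        a = train(small_feature_space, fast_som_config)
        b = train(small_feature_space, fast_som_config)
        np.testing.assert_array_equal(a.prototypes, b.prototypes)
        assert a.qe_history == b.qe_history
        c = train(small_feature_space, replace(fast_som_config, seed=99, init="random"))
        assert not np.array_equal(a.prototypes, c.prototypes)

    def test_empty_feature_space_raises(self):
        fs = _point_cloud_fs(np.zeros((0, 4)))
        with pytest.raises(ValueError):
            train(fs, SomConfig(lattice_shape=(2, 2, 1)))


class TestQuantizationError:
    def test_zero_when_prototypes_cover_data(self):
        X = np.arange(32, dtype=float).reshape(8, 4)
        model = _model_with(X, lattice_shape=(8, 1, 1))
        assert quantization_error(model, _point_cloud_fs(X)) == 0.0

    def test_single_prototype_midpoint(self):
        X = np.array([[0, 0, 0, 0], [2, 0, 0, 0]], dtype=float)
        model = _model_with(X.mean(axis=0, keepdims=True), lattice_shape=(1, 1, 1))
        assert quantization_error(model, _point_cloud_fs(X)) == 1.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(8)
        W = rng.standard_normal((12, 4))
        X = rng.standard_normal((40, 4))
        model = _model_with(W, lattice_shape=(12, 1, 1))
        ref = np.mean(
            [min(np.linalg.norm(x - w) for w in W) for x in X]
        )
        assert np.isclose(quantization_error(model, _point_cloud_fs(X)), ref, atol=1e-12)
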