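import numpy as np
import pytest

from irsom.som import HexSOM, assign_modules, compute_umatrix, hex_grid


class TestHexGrid:
    def test_7x7_has_49_nodes_and_hex_interior(self):
        coords, neighbors = hex_grid(7, 7)
        assert coords.shape == (49, 2)
        counts = [len(n) for n in neighbors]
        assert max(counts) == 6
        # interior nodes (away from every border) have exactly 6 neighbors
        interior = [
            k for k in range(49)
            if 0 < k // 7 < 6 and 0 < k % 7 < 6
        ]
        assert all(len(neighbors[k]) == 6 for k in interior)

    def test_1x1_single_node_no_neighbors(self):
        coords, neighbors = hex_grid(1, 1)
        assert coords.shape == (1, 2)
        assert neighbors == [[]]

    def test_2x2_every_node_has_at_least_two(self):
        _, neighbors = hex_grid(2, 2)
        assert all(len(n) >= 2 for n in neighbors)
        # adjacency is symmetric
        for i, ns in enumerate(neighbors):
            assert all(i in neighbors[j] for j in ns)


class TestInit:
    def test_sample_init_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 3))
        a = HexSOM(init="sample", random_state=7, epochs_ordering=1,
                   epochs_tuning=0, radius_start=1, radius_end=1).fit(X)
        b = HexSOM(init="sample", random_state=7, epochs_ordering=1,
                   epochs_tuning=0, radius_start=1, radius_end=1).fit(X)
        assert np.array_equal(a.codebook_, b.codebook_)

    def test_sample_init_short_data_pads_with_jitter(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        model = HexSOM(init="sample", random_state=0)
        codebook = model._init_codebook(X, np.random.default_rng(0))
        assert codebook.shape == (49, 3)
        assert np.isfinite(codebook).all()
        assert np.array_equal(codebook[:10], X)

    def test_pca_init_is_seed_free(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 3))
        a = HexSOM(random_state=1).fit(X).codebook_
        b = HexSOM(random_state=99).fit(X).codebook_
        assert np.array_equal(a, b)


class TestTraining:
    def test_single_module_converges_to_mean(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 3))
        model = HexSOM(rows=1, cols=1, epochs_ordering=1, epochs_tuning=0,
                       radius_start=0, radius_end=0, random_state=0).fit(X)
        assert model.codebook_[0] == pytest.approx(X.mean(axis=0))

    def test_two_separated_clouds_match_lloyd(self):
        """With sigma -> 0 a 2x1 SOM is 2-means; oracle = the cloud means."""
        rng = np.random.default_rng(4)
        a = rng.normal([0, 0, 0], 0.1, size=(100, 3))
        b = rng.normal([10, 10, 10], 0.1, size=(100, 3))
        X = np.vstack([a, b])
        model = HexSOM(rows=2, cols=1, epochs_ordering=5, epochs_tuning=20,
                       radius_start=0, radius_end=0, init="sample",
                       random_state=0).fit(X)
        got = model.codebook_[np.argsort(model.codebook_[:, 0])]
        assert got[0] == pytest.approx(a.mean(axis=0), abs=0.05)
        assert got[1] == pytest.approx(b.mean(axis=0), abs=0.05)

    def test_uniform_duplication_leaves_codebook_unchanged(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 3))
        base = HexSOM(rows=3, cols=3, random_state=0).fit(X).codebook_
        doubled = HexSOM(rows=3, cols=3, random_state=0).fit(
            np.vstack([X, X])
        ).codebook_
        assert doubled == pytest.approx(base, abs=1e-9)

    def test_kmeans_limit_distortion_nonincreasing(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(500, 3))
        model = HexSOM(epochs_ordering=25, epochs_tuning=25, epochs_polish=0,
                       radius_start=0, radius_end=0, init="sample",
                       random_state=0).fit(X)
        qe = np.array(model.quantization_errors_)
        assert len(qe) == 50
        assert np.all(np.diff(qe) <= 1e-12)

    def test_rejects_non_finite_data(self):
        X = np.array([[1.0, np.nan, 0.0]])
        with pytest.raises(ValueError):
            HexSOM().fit(X)


class TestAssignment:
    def test_exact_codebook_match_and_tie_to_lowest_index(self):
        rng = np.random.default_rng(7)
        model = HexSOM(rows=2, cols=2, epochs_ordering=1, epochs_tuning=0,
                       radius_start=1, radius_end=1, random_state=0)
        model.fit(rng.normal(size=(30, 2)))
        model.codebook_ = np.array(
            [[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]]
        )
        assert model.predict([[2.0, 0.0]])[0] == 1
        # (1, 0) is equidistant to modules 0 and 1 -> lowest index wins
        assert model.predict([[1.0, 0.0]])[0] == 0

    def test_assignment_partitions_data(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(300, 3))
        model = HexSOM(random_state=0).fit(X)
        ids = [f"T{i}" for i in range(len(X))]
        assignment = assign_modules(model, X, ids)
        assert len(assignment) == len(X)
        assert set(assignment.values()) <= set(range(1, 50))
        sizes = model.module_sizes(X)
        assert sizes.sum() == len(X)

    def test_quantization_error_examples(self):
        model = HexSOM(rows=1, cols=1, epochs_ordering=1, epochs_tuning=0,
                       radius_start=0, radius_end=0, random_state=0)
        model.fit(np.array([[0.0], [2.0]]))
        assert model.codebook_[0, 0] == pytest.approx(1.0)
        assert model.quantization_error(np.array([[0.0], [2.0]])) == pytest.approx(1.0)
        # data sitting exactly on codebook vectors has zero error
        assert model.quantization_error(np.array([[1.0]])) == 0.0


class TestUMatrix:
    def fitted(self, rows, cols, codebook):
        rng = np.random.default_rng(9)
        model = HexSOM(rows=rows, cols=cols, epochs_ordering=1, epochs_tuning=0,
                       radius_start=1, radius_end=1, random_state=0)
        model.fit(rng.normal(size=(max(rows * cols, 2), codebook.shape[1])))
        model.codebook_ = codebook.astype(float)
        return model

    def test_identical_codebooks_give_zero(self):
        model = self.fitted(2, 2, np.ones((4, 3)))
        um = compute_umatrix(model)
        assert all(v == 0 for v in um.pair_values.values())
        assert um.module_values.tolist() == [0.0] * 4

    def test_345_distance(self):
        model = self.fitted(2, 1, np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]]))
        um = compute_umatrix(model)
        assert um.pair_values[(0, 1)] == pytest.approx(5.0)
        assert um.module_values == pytest.approx([5.0, 5.0])

    def test_translation_invariance(self):
        rng = np.random.default_rng(10)
        codebook = rng.normal(size=(9, 3))
        a = compute_umatrix(self.fitted(3, 3, codebook))
        b = compute_umatrix(self.fitted(3, 3, codebook + 17.0))
        assert b.module_values == pytest.approx(a.module_values)

    def test_topology_preserved_on_manifold(self):
        """Lattice neighbors should be closer in data space than random pairs."""
        rng = np.random.default_rng(11)
        uv = rng.uniform(0, 4, size=(1500, 2))
        X = np.column_stack([uv[:, 0], uv[:, 1], 0.3 * uv[:, 0] + 0.1 * uv[:, 1]])
        model = HexSOM(random_state=0).fit(X)
        um = compute_umatrix(model)
        adjacent = np.mean(list(um.pair_values.values()))
        dists = []
        for _ in range(500):
            i, j = rng.choice(49, size=2, replace=False)
            if j not in model.neighbors_[i]:
                dists.append(np.linalg.norm(model.codebook_[i] - model.codebook_[j]))
        assert adjacent < np.mean(dists)


class TestDeterminism:
    def test_identical_inputs_identical_model(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(400, 3))
        a = HexSOM(random_state=3).fit(X)
        b = HexSOM(random_state=3).fit(X)
        assert np.array_equal(a.codebook_, b.codebook_)
        assert np.array_equal(a.labels_, b.labels_)
        assert a.quantization_errors_ == b.quantization_errors_
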