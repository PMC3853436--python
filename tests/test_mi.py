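import itertools

import numpy as np
import pandas as pd
import pytest

from mirhubnet import ExpressionMatrix, InputError
from mirhubnet.mi import (
    build_network,
    dpi_prune,
    ksg_mutual_information,
    pairwise_mi,
    permutation_mi_floor,
)


def brute_force_dpi_edges(mat, epsilon):
    """Independent oracle: enumerate every unordered triple explicitly."""
    m = mat.shape[0]
    removed = set()
    for i, j, k in itertools.combinations(range(m), 3):
        for (a, b), c in (((i, j), k), ((j, k), i), ((i, k), j)):
            if mat[a, b] < mat[b, c] - epsilon and mat[a, b] < mat[a, c] - epsilon:
                removed.add((min(a, b), max(a, b)))
    return {
        (i, j)
        for i, j in itertools.combinations(range(m), 2)
        if (i, j) not in removed and mat[i, j] > 0
    }


def _net_edge_index_set(net):
    return {tuple(sorted((int(a[1:]), int(b[1:])))) for a, b, _ in net.edges()}


class TestKsgEstimator:
    def test_symmetry_is_exact(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(100), rng.standard_normal(100)
        assert ksg_mutual_information(x, y) == ksg_mutual_information(y, x)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(1000), rng.standard_normal(1000)
        assert abs(ksg_mutual_information(x, y)) < 0.1

    def test_gaussian_closed_form_single_rho(self):
        rho, n = 0.8, 2000
        true = -0.5 * np.log(1 - rho**2)
        ests = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
            ests.append(ksg_mutual_information(z[:, 0], z[:, 1], 3, jitter_seed=seed))
        assert np.mean(ests) == pytest.approx(true, abs=0.05)

    def test_bias_shrinks_with_sample_size(self):
        """Gaussian MAE vs the closed form decreases from n=200 to n=2000."""
        rho = 0.8
        true = -0.5 * np.log(1 - rho**2)
        mae = {}
        for n in (200, 2000):
            errs = []
            for seed in range(8):
                rng = np.random.default_rng(seed)
                z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
                errs.append(abs(ksg_mutual_information(z[:, 0], z[:, 1]) - true))
            mae[n] = np.mean(errs)
        assert mae[2000] < mae[200]

    def test_constant_vector_returns_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            mi = ksg_mutual_information(np.ones(50), np.arange(50.0))
        assert mi == 0.0 and "constant" in caplog.text

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            ksg_mutual_information(np.arange(10.0), np.arange(11.0))

    def test_too_few_samples_rejected(self):
        with pytest.raises(InputError):
            ksg_mutual_information(np.arange(4.0), np.arange(4.0), k_neighbors=3)

    def test_deterministic_given_jitter_seed(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal(80), rng.standard_normal(80)
        assert ksg_mutual_information(x, y, jitter_seed=7) == ksg_mutual_information(
            x, y, jitter_seed=7
        )


class TestPairwiseMi:
    def _matrix(self, values):
        m, n = values.shape
        return ExpressionMatrix([f"f{i}" for i in range(m)], [f"s{j}" for j in range(n)], values)

    def test_two_features_single_value(self):
        rng = np.random.default_rng(3)
        mi = pairwise_mi(self._matrix(rng.standard_normal((2, 60))))
        assert mi.shape == (2, 2)
        assert mi.iloc[0, 1] == mi.iloc[1, 0]
        assert mi.iloc[0, 0] == 0.0

    def test_single_feature_empty_result(self):
        rng = np.random.default_rng(4)
        mi = pairwise_mi(self._matrix(rng.standard_normal((1, 60))))
        assert mi.shape == (1, 1) and mi.iloc[0, 0] == 0.0

    def test_duplicated_rows_dominate(self):
        """Self-information: a duplicated feature pair has the row's max MI."""
        rng = np.random.default_rng(5)
        base = rng.standard_normal(150)
        vals = np.vstack([base, base.copy(), rng.standard_normal((3, 150))])
        mi = pairwise_mi(self._matrix(vals))
        row = mi.iloc[0].drop("f0")
        assert row.idxmax() == "f1"


class TestDpiPrune:
    @staticmethod
    def _mat3(ab, bc, ac):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = ab
        m[1, 2] = m[2, 1] = bc
        m[0, 2] = m[2, 0] = ac
        return pd.DataFrame(m, index=list("ABC"), columns=list("ABC"))

    def test_weak_indirect_edge_removed(self):
        net = dpi_prune(self._mat3(2.0, 1.5, 0.4), epsilon=0.05)
        assert {(a, b) for a, b, _ in net.edges()} == {("A", "B"), ("B", "C")}

    def test_near_tie_triple_keeps_all_edges(self):
        net = dpi_prune(self._mat3(1.0, 0.98, 0.99), epsilon=0.05)
        assert net.n_edges == 3

    def test_asymmetric_input_rejected(self):
        m = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(InputError):
            dpi_prune(m)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            m = int(rng.integers(3, 13))
            a = rng.uniform(0, 2, size=(m, m))
            mat = np.triu(a, 1) + np.triu(a, 1).T
            net = dpi_prune(mat, epsilon=0.05)
            assert _net_edge_index_set(net) == brute_force_dpi_edges(mat, 0.05)

    def test_infinite_epsilon_removes_nothing(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0.1, 2, size=(6, 6))
        mat = np.triu(a, 1) + np.triu(a, 1).T
        net = dpi_prune(mat, epsilon=np.inf)
        assert net.n_edges == 15

    def test_never_adds_edges(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 1, size=(8, 8))
        mat = np.triu(a, 1) + np.triu(a, 1).T
        assert dpi_prune(mat, epsilon=0.01).n_edges <= 28


class TestBuildNetwork:
    def test_noise_features_give_sparse_or_empty_network(self):
        rng = np.random.default_rng(9)
        m = ExpressionMatrix(
            ["a", "b", "c"], [f"s{i}" for i in range(500)], rng.standard_normal((3, 500))
        )
        net = build_network(m, mi_floor="permutation", n_null=300, seed=0)
        assert net.n_edges <= 1

    def test_planted_module_resolves_to_hub_star(self):
        rng = np.random.default_rng(10)
        n = 300
        hub = rng.standard_normal(n)
        rho = 0.9
        members = rho * hub + np.sqrt(1 - rho**2) * rng.standard_normal((4, n))
        noise = rng.standard_normal((3, n))
        vals = np.vstack([hub, members, noise])
        ids = ["hub"] + [f"m{i}" for i in range(4)] + [f"z{i}" for i in range(3)]
        m = ExpressionMatrix(ids, [f"s{i}" for i in range(n)], vals)
        net = build_network(m, mi_floor="permutation", n_null=300, seed=1)
        for member in ("m0", "m1", "m2", "m3"):
            assert net.graph.has_edge("hub", member)
        # indirect member-member dependences are pruned by the DPI rule
        assert all(not net.graph.has_edge(f"m{i}", f"m{j}")
                   for i in range(4) for j in range(i + 1, 4))

    def test_single_feature_empty_network(self):
        rng = np.random.default_rng(11)
        m = ExpressionMatrix(["a"], [f"s{i}" for i in range(50)], rng.standard_normal((1, 50)))
        net = build_network(m)
        assert net.n_edges == 0 and net.n_nodes == 1

    def test_relabeling_features_gives_isomorphic_network(self):
        rng = np.random.default_rng(12)
        n = 200
        f = rng.standard_normal(n)
        vals = np.vstack([f, 0.95 * f + 0.3 * rng.standard_normal(n),
                          rng.standard_normal((2, n))])
        ids = ["w", "x", "y", "z"]
        m1 = ExpressionMatrix(ids, [f"s{i}" for i in range(n)], vals)
        perm = [2, 0, 3, 1]
        m2 = ExpressionMatrix([ids[i] for i in perm], m1.sample_ids, vals[perm])
        e1 = {frozenset((a, b)) for a, b, _ in build_network(m1, seed=3).edges()}
        e2 = {frozenset((a, b)) for a, b, _ in build_network(m2, seed=3).edges()}
        assert e1 == e2

    def test_params_recorded(self):
        rng = np.random.default_rng(13)
        m = ExpressionMatrix(["a", "b"], [f"s{i}" for i in range(60)],
                             rng.standard_normal((2, 60)))
        net = build_network(m, k_neighbors=4, epsilon=0.1)
        assert net.k_neighbors == 4 and net.epsilon == 0.1

    def test_permutation_floor_is_positive_and_deterministic(self):
        rng = np.random.default_rng(14)
        m = ExpressionMatrix([f"f{i}" for i in range(5)], [f"s{i}" for i in range(80)],
                             rng.standard_normal((5, 80)))
        f1 = permutation_mi_floor(m, n_null=200, seed=9)
        f2 = permutation_mi_floor(m, n_null=200, seed=9)
        assert f1 == f2 > 0
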