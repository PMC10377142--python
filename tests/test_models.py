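import numpy as np
import pytest
from sklearn.base import clone

from tripred._nn import sigmoid
from tripred.models import (
    EnsembleTripleClassifier,
    GTDTripleClassifier,
    MLPTripleClassifier,
    cp_reconstruct,
    ensemble_score,
    fuse_features,
    gtd_score,
    mlp_forward,
    mlp_score,
)


class TestFuseFeatures:
    def test_identity_configured_map_returns_concatenated_input(self, rng):
        id_emb = rng.normal(size=3)
        sim_row = rng.uniform(size=2)
        W = np.eye(5)
        out = fuse_features(id_emb, sim_row, W, np.zeros(5), activation="identity")
        assert np.allclose(out, np.concatenate([id_emb, sim_row]))

    @pytest.mark.parametrize("r", [8, 16, 32])
    def test_output_length_equals_rank(self, rng, r):
        W = rng.normal(size=(10, r))
        out = fuse_features(rng.normal(size=6), rng.uniform(size=4), W, np.zeros(r))
        assert out.shape == (r,)

    def test_zero_input_zero_weights_gives_bias(self):
        b = np.array([0.5, -1.0])
        out = fuse_features(np.zeros(2), np.zeros(3), np.zeros((5, 2)), b, "identity")
        assert np.allclose(out, b)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            fuse_features(np.zeros(2), np.zeros(3), np.zeros((4, 2)), np.zeros(2))


class TestGtdScore:
    def test_zero_latent_gives_half(self, rng):
        r = 4
        assert gtd_score(np.zeros(r), rng.normal(size=r), rng.normal(size=r), rng.normal(size=r)) == 0.5

    def test_zero_head_gives_half(self, rng):
        r = 4
        assert gtd_score(*rng.normal(size=(3, r)), np.zeros(r)) == 0.5

    @pytest.mark.parametrize("r", [1, 3, 8])
    def test_identity_head_one_equals_cp_triple_sum(self, rng, r):
        a, b, c = rng.normal(size=(3, r))
        expected = sum(a[q] * b[q] * c[q] for q in range(r))
        got = gtd_score(a, b, c, np.ones(r), activation="identity")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            gtd_score(np.zeros(3), np.zeros(4), np.zeros(3), np.zeros(3))

    def test_invariant_under_simultaneous_permutation(self, rng):
        r = 6
        a, b, c, h = rng.normal(size=(4, r))
        perm = rng.permutation(r)
        assert gtd_score(a, b, c, h) == pytest.approx(
            gtd_score(a[perm], b[perm], c[perm], h[perm]), abs=1e-12
        )


class TestCpReconstruct:
    def test_matches_brute_force_loops(self, rng):
        A, B, C = rng.normal(size=(3, 3)), rng.normal(size=(4, 3)), rng.normal(size=(2, 3))
        X = cp_reconstruct(A, B, C)
        for i in range(3):
            for j in range(4):
                for k in range(2):
                    expected = sum(A[i, q] * B[j, q] * C[k, q] for q in range(3))
                    assert X[i, j, k] == pytest.approx(expected, abs=1e-12)


class TestMlpForward:
    def test_single_identity_layer_is_noop(self, rng):
        z0 = rng.normal(size=4)
        out = mlp_forward([(np.eye(4), np.zeros(4), "identity")], z0)
        assert np.allclose(out, z0)

    def test_matches_loop_based_recomputation(self, rng):
        widths = [(5, 6), (6, 3), (3, 2)]
        layers = [
            (rng.normal(size=w), rng.normal(size=w[1]), "relu" if i < 2 else "identity")
            for i, w in enumerate(widths)
        ]
        z0 = rng.normal(size=5)
        z = z0.copy()
        for W, b, act in layers:  # independent per-layer recomputation
            pre = np.array([sum(z[m] * W[m, n] for m in range(W.shape[0])) + b[n] for n in range(W.shape[1])])
            z = np.maximum(pre, 0) if act == "relu" else pre
        assert np.allclose(mlp_forward(layers, z0), z)

    def test_relu_tower_all_negative_preactivation_gives_zero(self):
        W = -np.eye(3)
        out = mlp_forward([(W, np.zeros(3), "relu")], np.ones(3))
        assert np.all(out == 0)

    def test_width_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            mlp_forward([(np.zeros((4, 2)), np.zeros(2), "relu")], np.zeros(3))


class TestMlpScore:
    def _identity_tower(self, r):
        return [(np.eye(r), np.zeros(r), "identity")]

    def test_zero_tower_output_gives_half(self, rng):
        r = 4
        zero_tower = [(np.zeros((r, r)), np.zeros(r), "identity")]
        towers = [zero_tower, self._identity_tower(r), self._identity_tower(r)]
        assert mlp_score(towers, *rng.normal(size=(3, r)), rng.normal(size=r)) == 0.5

    def test_identity_towers_reduce_to_gtd_score(self, rng):
        r = 5
        a, b, c, h = rng.normal(size=(4, r))
        towers = [self._identity_tower(r)] * 3
        assert mlp_score(towers, a, b, c, h) == pytest.approx(gtd_score(a, b, c, h))

    def test_equals_chained_forward_and_gtd(self, rng):
        r = 4
        towers = [
            [(rng.normal(size=(r, 6)), rng.normal(size=6), "relu"),
             (rng.normal(size=(6, 3)), rng.normal(size=3), "identity")]
            for _ in range(3)
        ]
        a, b, c = rng.normal(size=(3, r))
        h = rng.normal(size=3)
        za, zb, zc = (mlp_forward(t, v) for t, v in zip(towers, (a, b, c)))
        assert mlp_score(towers, a, b, c, h) == pytest.approx(gtd_score(za, zb, zc, h))


class TestEnsembleScore:
    def test_zero_head_gives_half(self, rng):
        r = 4
        towers = [[(np.eye(r), np.zeros(r), "identity")]] * 3
        s = ensemble_score(rng.normal(size=(3, r)), rng.normal(size=(3, r)), towers, np.zeros(2 * r))
        assert s == 0.5

    def test_zero_mlp_half_reduces_to_gtd(self, rng):
        r = 4
        towers = [[(np.eye(r), np.zeros(r), "identity")]] * 3
        g = rng.normal(size=(3, r))
        m = rng.normal(size=(3, r))
        hg = rng.normal(size=r)
        h = np.concatenate([hg, np.zeros(r)])
        assert ensemble_score(g, m, towers, h) == pytest.approx(gtd_score(*g, hg))

    def test_equals_concatenated_interaction_recomputation(self, rng):
        r = 4
        towers = [
            [(rng.normal(size=(r, 2)), rng.normal(size=2), "identity")] for _ in range(3)
        ]
        g = rng.normal(size=(3, r))
        m = rng.normal(size=(3, r))
        h = rng.normal(size=r + 2)
        u_g = g[0] * g[1] * g[2]
        z = [mlp_forward(t, v) for t, v in zip(towers, m)]
        u = np.concatenate([u_g, z[0] * z[1] * z[2]])
        assert ensemble_score(g, m, towers, h) == pytest.approx(float(sigmoid(np.array(h @ u))))

    def test_wrong_head_length_raises(self, rng):
        r = 3
        towers = [[(np.eye(r), np.zeros(r), "identity")]] * 3
        with pytest.raises(ValueError):
            ensemble_score(rng.normal(size=(3, r)), rng.normal(size=(3, r)), towers, np.zeros(r))


@pytest.fixture(scope="module")
def tiny_problem():
    rng = np.random.default_rng(0)
    X = rng.integers(0, 6, size=(80, 3))
    y = rng.integers(0, 2, size=80).astype(float)
    sims = {
        role: np.eye(6) for role in ("drug", "gene", "disease")
    }
    return X, y, sims


class TestEstimators:
    @pytest.mark.parametrize("cls", [GTDTripleClassifier, MLPTripleClassifier, EnsembleTripleClassifier])
    def test_fit_predict_contract(self, cls, tiny_problem):
        X, y, sims = tiny_problem
        m = cls(rank=4, similarities=sims, max_epochs=5, min_epochs=1, random_state=0)
        m.fit(X, y)
        p = m.predict_proba(X)
        assert p.shape == (len(X), 2)
        assert np.all((p > 0) & (p < 1))
        assert np.allclose(p.sum(axis=1), 1)
        assert m.predict(X).shape == (len(X),)
        assert list(m.classes_) == [0, 1]

    @pytest.mark.parametrize("cls", [GTDTripleClassifier, MLPTripleClassifier, EnsembleTripleClassifier])
    def test_sklearn_clone_round_trip(self, cls):
        m = cls(rank=4, random_state=7)
        c = clone(m)
        assert c.get_params()["rank"] == 4
        assert c.get_params()["random_state"] == 7

    def test_fixed_seed_gives_identical_loss_trace(self, tiny_problem):
        X, y, sims = tiny_problem
        traces = []
        for _ in range(2):
            m = GTDTripleClassifier(rank=4, similarities=sims, max_epochs=8, min_epochs=1, random_state=3)
            m.fit(X, y)
            traces.append(m.history_["loss"])
        assert traces[0] == traces[1]

    def test_latent_vector_shapes(self, tiny_problem):
        X, y, sims = tiny_problem
        g = GTDTripleClassifier(rank=4, similarities=sims, max_epochs=3, min_epochs=1, random_state=0).fit(X, y)
        assert g.latent_vectors("drug").shape == (6, 4)
        e = EnsembleTripleClassifier(rank=4, similarities=sims, max_epochs=3, min_epochs=1, random_state=0).fit(X, y)
        assert e.latent_vectors("gene", path="gtd").shape == (6, 4)
        assert e.latent_vectors("gene", path="mlp").shape == (6, 2)
        assert e.latent_vectors("gene").shape == (6, 6)

    def test_gtd_estimator_matches_functional_composition(self, tiny_problem):
        X, y, sims = tiny_problem
        m = GTDTripleClassifier(rank=4, similarities=sims, max_epochs=3, min_epochs=1, random_state=1).fit(X, y)
        net = m.net_
        triple = X[0]
        lats = []
        for axis, role in enumerate(("drug", "gene", "disease")):
            emb = net.fusion.embeddings[axis].E[triple[axis]]
            sim_row = sims[role][triple[axis]]
            f = net.fusion.fusions[axis]
            lats.append(fuse_features(emb, sim_row, f.W, f.b, f.activation))
        expected = gtd_score(*lats, net.head.W[:, 0])
        assert m.predict_proba(triple[None, :])[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_invalid_labels_rejected(self, tiny_problem):
        X, _, sims = tiny_problem
        m = GTDTripleClassifier(rank=2, similarities=sims)
        with pytest.raises(ValueError):
            m.fit(X, np.full(len(X), 2.0))

    def test_out_of_range_index_rejected(self, tiny_problem):
        X, y, sims = tiny_problem
        m = GTDTripleClassifier(rank=2, similarities=sims)
        bad = X.copy()
        bad[0, 0] = 99
        with pytest.raises(ValueError):
            m.fit(bad, y)

    def test_nonincreasing_tower_widths_enforced(self, tiny_problem):
        X, y, sims = tiny_problem
        m = MLPTripleClassifier(rank=4, tower_widths=[2, 8], similarities=sims)
        with pytest.raises(ValueError):
            m.fit(X, y)


def test_cp_equivalence_on_exact_low_rank_tensor(rng):
    """Frozen factors with identity activation and unit head reproduce an
    exact rank-R tensor to numerical tolerance."""
    R, shape = 3, (6, 5, 4)
    A, B, C = (rng.uniform(size=(n, R)) for n in shape)
    X = cp_reconstruct(A, B, C)
    for i, j, k in rng.integers(0, 4, size=(10, 3)):
        s = gtd_score(A[i], B[j], C[k], np.ones(R), activation="identity")
        assert s == pytest.approx(X[i, j, k], abs=1e-9)
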