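"""The five classifiers: oracle equivalences, contracts, leakage, determinism."""

import numpy as np
import pytest
from numpy.polynomial import chebyshev as npcheb

from connbench import models as M
from connbench.autodiff import Tensor
from connbench.graphs import build_site_graph, scaled_laplacian


def _blobs(rng, n=200, d=4, sep=4.0):
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, d))
    X[:, 0] += sep * (y - 0.5)
    return X, y


def _fd_input_gradient(logit_fn, x, eps=1e-4):
    g = np.zeros_like(x)
    for j in range(x.size):
        e = np.zeros_like(x)
        e[j] = eps
        g[j] = (logit_fn(x + e) - logit_fn(x - e)) / (2 * eps)
    return g


class TestChebGconv:
    def test_k1_reduces_to_affine_map(self, rng):
        X = rng.normal(size=(5, 3))
        W = [rng.normal(size=(3, 2))]
        out = M.cheb_gconv(X, rng.normal(size=(5, 5)), W, K=1)
        assert np.allclose(out, X @ W[0])

    def test_zero_graph_k2_closed_form(self, rng):
        X = rng.normal(size=(4, 3))
        W = [rng.normal(size=(3, 2)) for _ in range(2)]
        out = M.cheb_gconv(X, -np.eye(4), W, K=2)
        assert np.allclose(out, X @ W[0] - X @ W[1])

    @pytest.mark.parametrize("K", [1, 2, 3, 4])
    def test_matches_dense_chebyshev_polynomials(self, K, rng):
        """Equivalence with explicitly evaluated matrix Chebyshev polynomials."""
        w = rng.random((6, 6))
        w = np.triu(w, 1)
        w = w + w.T
        L = scaled_laplacian(w)
        X = rng.normal(size=(6, 3))
        W = [rng.normal(size=(3, 2)) for _ in range(K)]
        expected = np.zeros((6, 2))
        for k in range(K):
            coeffs = np.zeros(k + 1)
            coeffs[k] = 1.0
            poly = npcheb.cheb2poly(coeffs)  # T_k in the monomial basis
            Tk = sum(c * np.linalg.matrix_power(L, i) for i, c in enumerate(poly))
            expected += Tk @ X @ W[k]
        out = M.cheb_gconv(X, L, W, K)
        assert np.abs(out - expected).max() < 1e-10

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            M.cheb_gconv(rng.normal(size=(4, 3)), np.eye(5), [np.eye(3)], K=1)


class TestSVM:
    def test_separable_blobs_reach_perfect_training_accuracy(self, rng):
        X, y = _blobs(rng, sep=8.0)
        m = M.train_svm(X, y, M.default_spec("svm", 4))
        assert (m.predict(X) == y).all()
        s = m.class_scores(X)
        assert np.allclose(s.sum(1), 1.0) and (s >= 0).all()

    def test_rbf_beats_linear_kernel_on_xor(self, rng):
        n = 1000
        X = rng.uniform(-1, 1, size=(n, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        tr, va = np.arange(0, 600), np.arange(600, n)
        m = M.train_svm(X[tr], y[tr], M.default_spec("svm", 2), X[va], y[va])
        rbf_acc = (m.predict(X[va]) == y[va]).mean()
        from sklearn.svm import SVC

        lin = SVC(kernel="linear").fit(X[tr], y[tr])
        lin_acc = (lin.predict(X[va]) == y[va]).mean()
        assert rbf_acc > 0.9 and lin_acc <= 0.6

    def test_duplicating_training_points_keeps_decision_function(self, rng):
        """On cleanly separable data the (hard-)margin solution is unchanged by
        duplicating every training point."""
        X, y = _blobs(rng, n=80, sep=8.0)
        spec = M.default_spec("svm", 4, C_grid=(1e4,))
        m1 = M.train_svm(X, y, spec)
        m2 = M.train_svm(np.vstack([X, X]), np.concatenate([y, y]), spec)
        grid = rng.normal(size=(50, 4))
        d1 = m1._svc.decision_function(grid)
        d2 = m2._svc.decision_function(grid)
        assert np.abs(d1 - d2).max() < 1e-4

    def test_single_class_labels_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            M.train_svm(X, np.zeros(10, dtype=int), M.default_spec("svm", 3))

    def test_input_gradient_unsupported(self, rng):
        X, y = _blobs(rng, n=40)
        m = M.train_svm(X, y, M.default_spec("svm", 4))
        with pytest.raises(NotImplementedError):
            m.input_gradient(X[0], 1)


class TestFCN:
    def test_separable_data_reaches_high_test_accuracy(self, rng):
        X, y = _blobs(rng, n=400, d=6, sep=4.0)
        spec = M.default_spec("fcn", 6, max_epochs=60, seed=0)
        m = M.train_fcn(X[:300], y[:300], spec, X[300:350], y[300:350])
        assert (m.predict(X[350:]) == y[350:]).mean() >= 0.95

    def test_permuted_labels_stay_at_chance(self, rng):
        X, y = _blobs(rng, n=700, d=6, sep=4.0)
        y_perm = rng.permutation(y)
        spec = M.default_spec("fcn", 6, max_epochs=40, seed=0)
        m = M.train_fcn(X[:400], y_perm[:400], spec, X[400:500], y_perm[400:500])
        acc = (m.predict(X[500:]) == y_perm[500:]).mean()
        assert abs(acc - 0.5) <= 0.08

    def test_eval_passes_are_bit_identical(self, rng):
        X, y = _blobs(rng, n=100)
        m = M.train_fcn(X, y, M.default_spec("fcn", 4, max_epochs=20))
        assert np.array_equal(m.class_scores(X), m.class_scores(X))

    def test_seeded_training_is_deterministic(self, rng):
        X, y = _blobs(rng, n=100)
        spec = M.default_spec("fcn", 4, max_epochs=20, seed=5)
        m1 = M.train_fcn(X, y, spec, X, y)
        m2 = M.train_fcn(X, y, spec, X, y)
        assert np.array_equal(m1.class_scores(X), m2.class_scores(X))

    def test_input_gradient_matches_finite_differences(self, rng):
        X, y = _blobs(rng, n=60)
        m = M.train_fcn(X, y, M.default_spec("fcn", 4, max_epochs=20))
        x0 = rng.normal(size=4)
        g = m.input_gradient(x0, 1)
        fd = _fd_input_gradient(lambda xx: m._logits(Tensor(xx.reshape(1, -1))).data[0, 1], x0)
        assert np.abs(g - fd).max() / np.abs(fd).max() < 1e-3


class TestAEFCN:
    def test_initial_loss_equals_hand_summed_mse_plus_ce(self, rng):
        X, y = _blobs(rng, n=50, d=8)
        spec = M.default_spec("ae_fcn", 8)
        model = M.AEFCNClassifier(spec, np.random.default_rng(spec.seed))
        recon, logits = model.forward(Tensor(X))
        mse = ((recon.data - X) ** 2).mean()
        p = np.exp(logits.data - logits.data.max(1, keepdims=True))
        p = p / p.sum(1, keepdims=True)
        ce = -np.log(p[np.arange(50), y]).mean()
        assert np.isclose(model.loss(Tensor(X), y).data, mse + ce, rtol=1e-10)

    def test_reconstruction_loss_decreases_without_classifier(self, rng):
        """With the CE term ablated, full-batch descent monotonically improves
        the reconstruction over the first epochs."""
        X, _ = _blobs(rng, n=40, d=8)
        spec = M.default_spec("ae_fcn", 8, ce_weight=0.0, lr=1e-3)
        model = M.AEFCNClassifier(spec, np.random.default_rng(0))
        from connbench.autodiff import Adam

        opt = Adam(model.params, lr=spec.lr, weight_decay=0.0)
        mses = []
        for _ in range(10):
            loss = model.loss(Tensor(X), np.zeros(40, dtype=int))
            mses.append(float(loss.data))
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert all(b < a for a, b in zip(mses, mses[1:]))

    def test_separable_data_reaches_high_accuracy(self, rng):
        X, y = _blobs(rng, n=300, d=8, sep=5.0)
        spec = M.default_spec("ae_fcn", 8, max_epochs=80)
        m = M.train_ae_fcn(X[:200], y[:200], spec, X[200:250], y[200:250])
        assert (m.predict(X[250:]) == y[250:]).mean() >= 0.9

    def test_input_gradient_matches_finite_differences(self, rng):
        X, y = _blobs(rng, n=50, d=5)
        m = M.train_ae_fcn(X, y, M.default_spec("ae_fcn", 5, max_epochs=20))
        x0 = rng.normal(size=5)
        g = m.input_gradient(x0, 0)
        fd = _fd_input_gradient(lambda xx: m._logits(Tensor(xx.reshape(1, -1))).data[0, 0], x0)
        assert np.abs(g - fd).max() / np.abs(fd).max() < 1e-3


def _transductive_setup(rng, n=90, d=5):
    sites = np.array([f"S{i % 6}" for i in range(n)])
    w = rng.normal(size=d)
    X = rng.normal(size=(n, d))
    y = (X @ w > 0).astype(int)
    idx = rng.permutation(n)
    masks = {"train": idx[: n // 2], "val": idx[n // 2 : 3 * n // 4], "test": idx[3 * n // 4 :]}
    return X, y, sites, masks


class TestGCN:
    def test_zero_graph_predictions_depend_only_on_own_features(self, rng):
        """With an empty graph the Chebyshev filter collapses to a per-node
        map: changing every other node's features leaves a prediction fixed."""
        X, y, sites, masks = _transductive_setup(rng)
        L = -np.eye(len(y))  # scaled Laplacian of the empty graph
        spec = M.default_spec("gcn", 5, max_epochs=30)
        m = M.train_gcn(X, L, y, masks, spec)
        node = int(masks["test"][0])
        before = m.class_scores([node])[0].copy()
        m.X_all = m.X_all.copy()
        other = np.ones(len(y), dtype=bool)
        other[node] = False
        m.X_all[other] += rng.normal(size=(other.sum(), 5))
        m._cache = None
        after = m.class_scores([node])[0]
        assert np.allclose(before, after, atol=1e-12)

    def test_site_aligned_labels_recovered_through_graph(self, rng):
        n = 180
        sites = np.array([f"S{i % 6}" for i in range(n)])
        y = np.array([int(s[1]) % 2 for s in sites])
        X = rng.normal(size=(n, 5))  # features carry no label signal
        idx = rng.permutation(n)
        masks = {"train": idx[:108], "val": idx[108:144], "test": idx[144:]}
        L = scaled_laplacian(build_site_graph(sites))
        m = M.train_gcn(X, L, y, masks, M.default_spec("gcn", 5, max_epochs=100))
        acc = (m.class_scores(masks["test"]).argmax(1) == y[masks["test"]]).mean()
        assert acc >= 0.9

    def test_test_label_perturbation_leaves_weights_bit_identical(self, rng):
        X, y, sites, masks = _transductive_setup(rng)
        L = scaled_laplacian(build_site_graph(sites))
        spec = M.default_spec("gcn", 5, max_epochs=30)
        m1 = M.train_gcn(X, L, y, masks, spec)
        y2 = y.copy()
        y2[masks["test"]] = 1 - y2[masks["test"]]
        m2 = M.train_gcn(X, L, y2, masks, spec)
        for p1, p2 in zip(m1.params, m2.params):
            assert np.array_equal(p1.data, p2.data)

    def test_mask_overlap_rejected(self, rng):
        X, y, sites, masks = _transductive_setup(rng)
        masks["val"] = np.concatenate([masks["val"], masks["test"][:1]])
        masks["test"] = masks["test"]
        bad = dict(masks)
        bad["train"] = np.concatenate([bad["train"], bad["test"][:1]])
        L = scaled_laplacian(build_site_graph(sites))
        with pytest.raises(ValueError, match="overlap"):
            M.train_gcn(X, L, y, bad, M.default_spec("gcn", 5, max_epochs=10))

    def test_input_gradient_matches_finite_differences(self, rng):
        X, y, sites, masks = _transductive_setup(rng, n=40)
        L = scaled_laplacian(build_site_graph(sites[:40]))
        m = M.train_gcn(X, L, y, masks, M.default_spec("gcn", 5, max_epochs=20))
        node = 7
        g = m.input_gradient(node, 1)

        def f(xx):
            Xc = m.X_all.copy()
            Xc[node] = xx
            return m._forward_all(Tensor(Xc)).data[node, 1]

        fd = _fd_input_gradient(f, X[node].copy())
        assert np.abs(g - fd).max() / np.abs(fd).max() < 1e-3


class TestEVGCN:
    def _pheno(self, rng, sites):
        sex = rng.integers(0, 2, len(sites))
        cats = sorted(set(sites))
        site_oh = (np.asarray(sites)[:, None] == np.array(cats)[None, :]).astype(float)
        return np.column_stack([sex, 1 - sex, site_oh])

    def test_fusion_concatenates_four_16_channel_outputs(self, rng):
        X, y, sites, masks = _transductive_setup(rng, n=30)
        spec = M.default_spec("ev_gcn", 5)
        m = M.EVGCNClassifier(spec, self._pheno(rng, sites[:30]), X, np.random.default_rng(0))
        W = Tensor(m.pae.weights(m.pheno).data)
        L = m._laplacian_from_weights(W)
        outs = []
        h = Tensor(X)
        for g in m.gcs:
            h = g(L, h).relu()
            outs.append(h)
        from connbench.autodiff import concat

        fused = concat(outs, axis=1)
        assert fused.shape == (30, 64) and all(o.shape[1] == 16 for o in outs)

    def test_trainable_pae_not_worse_than_frozen(self, rng):
        X, y, sites, masks = _transductive_setup(rng, n=90)
        pheno = self._pheno(rng, sites)
        spec = M.default_spec("ev_gcn", 5, max_epochs=40)
        m_train = M.train_ev_gcn(X, pheno, y, masks, spec)
        frozen = M.EVGCNClassifier(spec, pheno, X, np.random.default_rng(spec.seed))
        frozen.train_pae = False
        m_frozen = M._train_transductive(frozen, y, masks, spec, None)
        va = masks["val"]
        acc_t = (m_train.class_scores(va).argmax(1) == y[va]).mean()
        acc_f = (m_frozen.class_scores(va).argmax(1) == y[va]).mean()
        assert acc_t >= acc_f - 0.05

    def test_eval_mode_is_deterministic(self, rng):
        X, y, sites, masks = _transductive_setup(rng, n=40)
        m = M.train_ev_gcn(
            X, self._pheno(rng, sites[:40]), y, masks, M.default_spec("ev_gcn", 5, max_epochs=20)
        )
        s1 = m.class_scores(masks["test"])
        m._cache = None
        s2 = m.class_scores(masks["test"])
        assert np.array_equal(s1, s2)
        assert np.allclose(s1.sum(1), 1.0)

    def test_input_gradient_matches_finite_differences(self, rng):
        X, y, sites, masks = _transductive_setup(rng, n=30)
        m = M.train_ev_gcn(
            X, self._pheno(rng, sites[:30]), y, masks, M.default_spec("ev_gcn", 5, max_epochs=10)
        )
        node = 3
        g = m.input_gradient(node, 1)

        def f(xx):
            Xc = m.X_all.copy()
            Xc[node] = xx
            return m._forward_all(Tensor(Xc)).data[node, 1]

        fd = _fd_input_gradient(f, X[node].copy())
        assert np.abs(g - fd).max() / np.abs(fd).max() < 1e-3


class TestCheckpoints:
    def test_feedforward_round_trip_is_bit_identical(self, rng, tmp_path):
        X, y = _blobs(rng, n=60, d=5)
        for arch, trainer in (("fcn", M.train_fcn), ("ae_fcn", M.train_ae_fcn)):
            m = trainer(X, y, M.default_spec(arch, 5, max_epochs=20), X, y)
            path = tmp_path / f"{arch}.npz"
            M.save_model(m, path)
            back = M.load_model(path)
            assert np.array_equal(back.class_scores(X), m.class_scores(X))
            assert back.selected == m.selected

    def test_transductive_round_trip_is_bit_identical(self, rng, tmp_path):
        X, y, sites, masks = _transductive_setup(rng, n=50)
        L = scaled_laplacian(build_site_graph(sites[:50]))
        m = M.train_gcn(X, L, y, masks, M.default_spec("gcn", 5, max_epochs=20))
        M.save_model(m, tmp_path / "gcn.npz")
        back = M.load_model(tmp_path / "gcn.npz")
        idx = masks["test"]
        assert np.array_equal(back.class_scores(idx), m.class_scores(idx))

    def test_ev_gcn_round_trip_preserves_pae_graph(self, rng, tmp_path):
        X, y, sites, masks = _transductive_setup(rng, n=40)
        pheno = TestEVGCN()._pheno(rng, sites[:40])
        m = M.train_ev_gcn(X, pheno, y, masks, M.default_spec("ev_gcn", 5, max_epochs=10))
        M.save_model(m, tmp_path / "ev.npz")
        back = M.load_model(tmp_path / "ev.npz")
        idx = masks["test"]
        assert np.array_equal(back.class_scores(idx), m.class_scores(idx))

    def test_svm_is_not_serializable(self, rng, tmp_path):
        X, y = _blobs(rng, n=40)
        m = M.train_svm(X, y, M.default_spec("svm", 4))
        with pytest.raises(NotImplementedError):
            M.save_model(m, tmp_path / "svm.npz")


class TestContracts:
    def test_nan_loss_aborts_with_diagnostics(self, rng):
        X, y = _blobs(rng, n=30)
        X[0, 0] = np.nan
        with pytest.raises(RuntimeError, match="non-finite"):
            M.train_fcn(X, y, M.default_spec("fcn", 4, max_epochs=10))

    @pytest.mark.parametrize("arch", ["fcn", "ae_fcn"])
    def test_class_scores_sum_to_one(self, arch, rng):
        X, y = _blobs(rng, n=60, d=5)
        trainer = M.train_fcn if arch == "fcn" else M.train_ae_fcn
        m = trainer(X, y, M.default_spec(arch, 5, max_epochs=20))
        assert np.abs(m.class_scores(X).sum(1) - 1.0).max() < 1e-6
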