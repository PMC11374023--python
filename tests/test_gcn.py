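import numpy as np
import pytest

import psnfuse as pf
from psnfuse.gcn import _glorot, gcn_forward
from oracles import gcn_forward_nodewise, laplacian_entrywise


def two_modality_setup(rng, n=12, missing_in_b=(2, 5)):
    """Small union problem: modality A observes everyone, B misses two."""
    ids = [f"p{i:02d}" for i in range(n)]
    a = pf.OmicsMatrix("A", ids, [f"a{j}" for j in range(6)],
                       rng.normal(size=(n, 6)), "continuous")
    b_ids = [p for i, p in enumerate(ids) if i not in missing_in_b]
    b = pf.OmicsMatrix("B", b_ids, [f"b{j}" for j in range(5)],
                       rng.normal(size=(len(b_ids), 5)), "continuous")
    man = pf.build_manifest([a, b])
    w = np.zeros((n, n))
    for i in range(n - 1):  # path graph keeps everything connected
        w[i, i + 1] = w[i + 1, i] = 1.0
    graph = pf.PatientGraph(ids, w)
    y = np.array([i % 2 for i in range(n)])
    return [a, b], man, graph, y


def small_model(mats, man, seed=0, **kw):
    labels = pf.LabelSet(man.union_ids,
                         ["A" if i % 2 == 0 else "B" for i in range(man.n_patients)])
    cfg = pf.RunConfig(encoder_hidden=7, latent_dim=4, shared_dim=3, gcn_hidden=5,
                       seed=seed, **kw)
    return pf.build_model(mats, man, labels, cfg)


class TestEncoder:
    def test_zero_weights_give_zero_latent(self):
        w = {"W1": np.zeros((4, 3)), "b1": np.zeros(3),
             "W2": np.zeros((3, 2)), "b2": np.zeros(2)}
        out = pf.encode_modality(np.ones((5, 4)), w)
        np.testing.assert_array_equal(out, 0.0)

    def test_identity_weights_linear_activation(self, rng):
        x = rng.normal(size=(4, 3))
        w = {"W1": np.eye(3), "b1": np.zeros(3),
             "W2": np.eye(3), "b2": np.zeros(3)}
        np.testing.assert_allclose(pf.encode_modality(x, w, activation="linear"), x)

    def test_matches_composed_matrix_product(self, rng):
        x = rng.normal(size=(6, 10))
        w = {"W1": rng.normal(size=(10, 7)), "b1": rng.normal(size=7),
             "W2": rng.normal(size=(7, 3)), "b2": rng.normal(size=3)}
        expected = np.maximum(x @ w["W1"] + w["b1"], 0) @ w["W2"] + w["b2"]
        np.testing.assert_allclose(pf.encode_modality(x, w), expected, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        w = {"W1": np.zeros((4, 3)), "b1": np.zeros(3),
             "W2": np.zeros((3, 2)), "b2": np.zeros(2)}
        with pytest.raises(ValueError, match="dimension"):
            pf.encode_modality(np.ones((5, 6)), w)


class TestMedianImputation:
    def _manifest(self, observed_ids, missing_ids, modality="B"):
        import pandas as pd
        union = sorted(observed_ids + missing_ids)
        obs = pd.DataFrame({"A": [True] * len(union),
                            modality: [u in observed_ids for u in union]},
                           index=union)
        return pf.SampleManifest(union, obs)

    def test_odd_count_median_row(self):
        man = self._manifest(["p1", "p2", "p3"], ["p4"])
        lat = np.array([[1.0, 2], [3, 4], [5, 6]])
        full = pf.impute_missing_latent(lat, man, "B")
        np.testing.assert_array_equal(full[man.union_ids.index("p4")], [3.0, 4.0])

    def test_even_count_midpoint_median(self):
        man = self._manifest(["p1", "p2"], ["p3"])
        full = pf.impute_missing_latent(np.array([[1.0, 2], [3, 4]]), man, "B")
        np.testing.assert_array_equal(full[man.union_ids.index("p3")], [2.0, 3.0])

    def test_all_observed_identity(self, rng):
        man = self._manifest(["p1", "p2", "p3"], [])
        lat = rng.normal(size=(3, 4))
        np.testing.assert_array_equal(pf.impute_missing_latent(lat, man, "B"), lat)

    def test_imputed_rows_match_columnwise_medians(self, rng):
        obs = [f"p{i:02d}" for i in range(9)]
        man = self._manifest(obs, ["q1", "q2"])
        lat = rng.normal(size=(9, 5))
        full = pf.impute_missing_latent(lat, man, "B")
        for q in ("q1", "q2"):
            np.testing.assert_array_equal(full[man.union_ids.index(q)],
                                          np.median(lat, axis=0))


class TestPooling:
    def test_single_modality_equals_projection(self, rng):
        z = rng.normal(size=(5, 3))
        W, b = rng.normal(size=(3, 2)), rng.normal(size=2)
        np.testing.assert_allclose(pf.pool_shared_latent([z], [(W, b)]), z @ W + b)

    def test_identical_projections_idempotent(self, rng):
        z = rng.normal(size=(5, 3))
        W, b = rng.normal(size=(3, 2)), rng.normal(size=2)
        out = pf.pool_shared_latent([z, z], [(W, b), (W, b)])
        np.testing.assert_allclose(out, z @ W + b)

    def test_opposite_latents_cancel(self, rng):
        z = rng.normal(size=(4, 3))
        W = rng.normal(size=(3, 2))
        out = pf.pool_shared_latent([z, -z], [(W, np.zeros(2)), (W, np.zeros(2))])
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_mismatched_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="patient count"):
            pf.pool_shared_latent([rng.normal(size=(4, 2)), rng.normal(size=(5, 2))],
                                  [(np.eye(2), np.zeros(2))] * 2)


class TestLaplacian:
    def test_edgeless_graph_gives_identity(self):
        np.testing.assert_array_equal(pf.normalized_laplacian(np.zeros((4, 4))),
                                      np.eye(4))

    def test_single_edge_all_entries_half(self):
        A = np.array([[0.0, 1], [1, 0]])
        np.testing.assert_allclose(pf.normalized_laplacian(A), 0.5)

    def test_random_graphs_match_entrywise_formula(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 13))
            A = (rng.random((n, n)) < 0.4).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            np.testing.assert_allclose(pf.normalized_laplacian(A),
                                       laplacian_entrywise(A), atol=1e-12)

    def test_asymmetric_rejected(self):
        A = np.array([[0.0, 1], [0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            pf.normalized_laplacian(A)


class TestGcnForward:
    def _weights(self, rng, d, h, c):
        return {"W0": rng.normal(size=(d, h)), "b0": rng.normal(size=h),
                "W1": rng.normal(size=(h, c)), "b1": rng.normal(size=c)}

    def test_edgeless_reduces_to_dense_network(self, rng):
        X = rng.normal(size=(5, 3))
        w = self._weights(rng, 3, 4, 2)
        logits = gcn_forward(X, np.eye(5), w)
        dense = np.maximum(X @ w["W0"] + w["b0"], 0) @ w["W1"] + w["b1"]
        np.testing.assert_allclose(logits, dense, atol=1e-12)

    def test_zero_weights_zero_logits(self, rng):
        X = rng.normal(size=(4, 3))
        w = {"W0": np.zeros((3, 4)), "b0": np.zeros(4),
             "W1": np.zeros((4, 2)), "b1": np.zeros(2)}
        L = pf.normalized_laplacian(np.zeros((4, 4)))
        np.testing.assert_array_equal(gcn_forward(X, L, w), 0.0)

    def test_matches_nodewise_message_passing_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 13))
            A = np.triu((rng.random((n, n)) < 0.5).astype(float), 1)
            A = A + A.T
            X = rng.normal(size=(n, 4))
            w = self._weights(rng, 4, 6, 3)
            logits = gcn_forward(X, pf.normalized_laplacian(A), w)
            expected = gcn_forward_nodewise(X, A, w["W0"], w["b0"], w["W1"], w["b1"])
            np.testing.assert_allclose(logits, expected, atol=1e-6)

    def test_nonfinite_input_raises_with_layer(self, rng):
        X = rng.normal(size=(3, 2))
        w = self._weights(rng, 2, 3, 2)
        w["W1"][0, 0] = np.inf
        with pytest.raises(FloatingPointError, match="layer"):
            gcn_forward(X, np.eye(3), w)


class TestMaskedLoss:
    def test_uniform_logits_log_C(self):
        logits = np.ones((6, 4))
        y = np.array([0, 1, 2, 3, 0, 1])
        mask = np.array([True] * 6)
        assert pf.masked_cross_entropy(logits, y, mask) == pytest.approx(np.log(4))

    def test_unmasked_labels_are_inert_bitwise(self, rng):
        logits = rng.normal(size=(8, 3))
        y = rng.integers(0, 3, size=8)
        mask = np.array([True, True, False, False, True, False, False, True])
        loss1 = pf.masked_cross_entropy(logits, y, mask)
        y2 = y.copy()
        y2[~mask] = (y2[~mask] + 1) % 3
        assert pf.masked_cross_entropy(logits, y2, mask) == loss1

    def test_two_masked_nodes_hand_computed(self):
        logits = np.array([[2.0, 0.0], [0.0, 1.0], [5.0, 5.0]])
        y = np.array([0, 1, 0])
        mask = np.array([True, True, False])
        e0 = -np.log(np.exp(2) / (np.exp(2) + 1))
        e1 = -np.log(np.exp(1) / (np.exp(1) + 1))
        assert pf.masked_cross_entropy(logits, y, mask) == pytest.approx((e0 + e1) / 2)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no nodes"):
            pf.masked_cross_entropy(np.ones((2, 2)), [0, 1], [False, False])


class TestBackprop:
    def test_gradients_match_finite_differences(self, rng):
        # fully observed: the median-imputation constant never engages,
        # so analytic and numerical gradients must agree everywhere
        mats, man, graph, y = two_modality_setup(rng, n=7, missing_in_b=())
        model = small_model(mats, man)
        inputs = pf.GcnMme.prepare_inputs(mats, man)
        L = pf.normalized_laplacian(graph.adjacency)
        mask = np.array([True, True, False, True, True, False, True])
        logits, cache = model.forward(inputs, L, train=True)
        grads = model.backward(logits, cache, y, mask)
        eps = 1e-6
        for key in ["A/W1", "B/W2", "A/W3", "gcn/W0", "gcn/W1", "gcn/b0"]:
            g = grads[key]
            if g.ndim == 2:
                probe = [(0, 0), (g.shape[0] // 2, g.shape[1] // 2)]
            else:
                probe = [(0,), (g.shape[0] // 2,)]
            for idx in probe:
                orig = model.params[key][idx]
                model.params[key][idx] = orig + eps
                lp, _ = model.forward(inputs, L, train=True)
                fplus = pf.masked_cross_entropy(lp, y, mask)
                model.params[key][idx] = orig - eps
                lm, _ = model.forward(inputs, L, train=True)
                fminus = pf.masked_cross_entropy(lm, y, mask)
                model.params[key][idx] = orig
                num = (fplus - fminus) / (2 * eps)
                assert g[idx] == pytest.approx(num, abs=2e-5), key

    def test_batchnorm_gradients_match_finite_differences(self, rng):
        mats, man, graph, y = two_modality_setup(rng, n=12)
        model = small_model(mats, man)
        inputs = pf.GcnMme.prepare_inputs(mats, man)
        L = pf.normalized_laplacian(graph.adjacency)
        mask = np.ones(12, dtype=bool)
        logits, cache = model.forward(inputs, L, train=True)
        assert cache["bn"]
        grads = model.backward(logits, cache, y, mask)
        eps = 1e-6
        for key in ["gcn/gamma", "gcn/beta", "gcn/W0"]:
            idx = (0,) if model.params[key].ndim == 1 else (0, 0)
            orig = model.params[key][idx]
            bn_state = (model.bn_running_mean.copy(), model.bn_running_var.copy())
            model.params[key][idx] = orig + eps
            lp, _ = model.forward(inputs, L, train=True)
            fplus = pf.masked_cross_entropy(lp, y, mask)
            model.params[key][idx] = orig - eps
            lm, _ = model.forward(inputs, L, train=True)
            fminus = pf.masked_cross_entropy(lm, y, mask)
            model.params[key][idx] = orig
            model.bn_running_mean, model.bn_running_var = bn_state
            num = (fplus - fminus) / (2 * eps)
            assert grads[key][idx] == pytest.approx(num, abs=2e-5), key


class TestTraining:
    def _masks(self, n):
        train = np.zeros(n, dtype=bool); train[: n // 2] = True
        val = np.zeros(n, dtype=bool); val[n // 2: 3 * n // 4] = True
        test = np.zeros(n, dtype=bool); test[3 * n // 4:] = True
        return pf.Masks(train, val, test)

    def test_loss_decreases_on_separable_data(self, rng):
        mats, man, graph, y = two_modality_setup(rng, n=12)
        # plant signal: class shifts feature means in modality A
        mats[0].values[y == 1] += 2.0
        model = small_model(mats, man)
        inputs = pf.GcnMme.prepare_inputs(mats, man)
        model.fit(inputs, graph, y, self._masks(12), max_epochs=120, patience=120)
        h = model.history["train_loss"]
        assert h[-1] < h[0]

    def test_same_seed_bit_identical_histories(self, rng):
        mats, man, graph, y = two_modality_setup(rng, n=12)
        runs = []
        for _ in range(2):
            model = small_model(mats, man, seed=5)
            inputs = pf.GcnMme.prepare_inputs(mats, man)
            model.fit(inputs, graph, y, self._masks(12), max_epochs=30, patience=30)
            runs.append(model)
        assert runs[0].history == runs[1].history
        for k in runs[0].params:
            np.testing.assert_array_equal(runs[0].params[k], runs[1].params[k])

    def test_test_labels_never_touch_training(self, rng):
        """Bit-level transductive integrity over one epoch of updates."""
        mats, man, graph, y = two_modality_setup(rng, n=12)
        masks = self._masks(12)
        states = []
        for flip_test in (False, True):
            y2 = y.copy()
            if flip_test:
                y2[masks.test] = 1 - y2[masks.test]
            model = small_model(mats, man, seed=3)
            inputs = pf.GcnMme.prepare_inputs(mats, man)
            model.fit(inputs, graph, y2, masks, max_epochs=1, patience=10)
            states.append((model.history["train_loss"][0],
                           model.history["val_loss"][0],
                           {k: v.copy() for k, v in model.params.items()}))
        assert states[0][0] == states[1][0]
        assert states[0][1] == states[1][1]
        for k in states[0][2]:
            np.testing.assert_array_equal(states[0][2][k], states[1][2][k])


class TestPredict:
    def _trained(self, rng):
        mats, man, graph, y = two_modality_setup(rng, n=12)
        mats[0].values[y == 1] += 2.0
        model = small_model(mats, man)
        inputs = pf.GcnMme.prepare_inputs(mats, man)
        n = 12
        train = np.zeros(n, dtype=bool); train[:8] = True
        val = np.zeros(n, dtype=bool); val[8:10] = True
        test = np.zeros(n, dtype=bool); test[10:] = True
        model.fit(inputs, graph, y, pf.Masks(train, val, test),
                  max_epochs=80, patience=80)
        return model, inputs, graph, man

    def test_probability_rows_sum_to_one(self, rng):
        model, inputs, graph, _ = self._trained(rng)
        _, probs = model.predict(inputs, graph)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_predictions_are_known_classes_and_cover_union(self, rng):
        model, inputs, graph, man = self._trained(rng)
        pred, _ = model.predict(inputs, graph)
        assert pred.shape == (man.n_patients,)
        assert set(np.unique(pred)) <= {0, 1}

    def test_untrained_model_refuses(self, rng):
        mats, man, graph, _ = two_modality_setup(rng, n=12)
        model = small_model(mats, man)
        with pytest.raises(RuntimeError, match="train"):
            model.predict(pf.GcnMme.prepare_inputs(mats, man), graph)

    def test_permutation_equivariance_eval_mode(self, rng):
        model, inputs, graph, man = self._trained(rng)
        _, probs = model.predict(inputs, graph)
        n = man.n_patients
        perm = rng.permutation(n)
        # permute union order in every aligned structure
        L = pf.normalized_laplacian(graph.adjacency)
        perm_inputs = []
        for (x, observed) in inputs:
            pos_in_obs = np.cumsum(observed) - 1  # union idx -> row in x
            new_obs = observed[perm]
            rows = [pos_in_obs[i] for i in perm if observed[i]]
            perm_inputs.append((x[rows], new_obs))
        Wp = graph.weights[np.ix_(perm, perm)]
        graph_p = pf.PatientGraph([graph.patient_ids[i] for i in perm], Wp)
        _, probs_p = model.predict(perm_inputs, graph_p)
        np.testing.assert_allclose(probs_p, probs[perm], atol=1e-10)
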