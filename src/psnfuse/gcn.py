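"""The GCN-MME: multi-modal encoders feeding a transductive graph
convolutional network, trained jointly.

Each modality is encoded by a two-layer network (hidden width D, default
500; latent width tuned per modality). Patients missing from a modality
receive the per-dimension median of the observed patients' latent rows, so
every union patient has a full set of latents. Latents are projected to a
shared dimension d and mean-pooled across modalities into the node feature
matrix X. Two graph convolutions

    H(l+1) = sigma(L H(l) W(l)),   L = D̃^(-1/2) Ã D̃^(-1/2),  Ã = A + I

with an intermediate ReLU + batch norm map X to class logits. Training
minimizes cross-entropy over training nodes only: validation and test
nodes participate in message passing but never in the loss (transductive
semi-supervised training).

The network, its gradients, and the Adam optimizer are implemented
directly in numpy; a single integer seed makes runs bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import LabelSet, OmicsMatrix, PatientGraph, SampleManifest

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class EncoderSpec:
    """Shape of one modality's two-layer encoder."""

    modality_name: str
    input_dim: int
    hidden_dim: int = 500
    latent_dim: int = 32

    def __post_init__(self):
        if not (self.input_dim >= self.latent_dim >= 1):
            raise ValueError(
                f"{self.modality_name}: need input_dim >= latent_dim >= 1 "
                f"(got {self.input_dim} and {self.latent_dim})"
            )
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")


@dataclass
class Masks:
    """Disjoint boolean train / validation / test node masks over the union."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def __post_init__(self):
        self.train = np.asarray(self.train, dtype=bool)
        self.val = np.asarray(self.val, dtype=bool)
        self.test = np.asarray(self.test, dtype=bool)
        if not (self.train.shape == self.val.shape == self.test.shape):
            raise ValueError("mask shapes differ")
        overlap = (self.train & self.val) | (self.train & self.test) | (self.val & self.test)
        if overlap.any():
            raise ValueError("train/val/test masks must be mutually exclusive")

    @property
    def n(self) -> int:
        return self.train.size


# ---------------------------------------------------------------------------
# Functional building blocks (stateless; the model class composes them)


def encode_modality(values: np.ndarray, weights: dict, activation: str = "relu") -> np.ndarray:
    """Two-layer encoder forward pass: layer2(act(layer1(values)))."""
    x = np.asarray(values, dtype=float)
    W1, b1, W2, b2 = weights["W1"], weights["b1"], weights["W2"], weights["b2"]
    if x.shape[1] != W1.shape[0]:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match encoder input {W1.shape[0]}"
        )
    a1 = x @ W1 + b1
    z1 = np.maximum(a1, 0.0) if activation == "relu" else a1
    return z1 @ W2 + b2


def impute_missing_latent(latent: np.ndarray, manifest: SampleManifest,
                          modality: str) -> np.ndarray:
    """Expand an observed-patients latent matrix to the union via medians.

    Rows for patients the modality did not measure are filled with the
    per-dimension median over the observed patients' latent rows (midpoint
    convention for even counts).
    """
    latent = np.asarray(latent, dtype=float)
    observed = manifest.observed[modality].to_numpy()
    if latent.shape[0] != observed.sum():
        raise ValueError(
            f"latent has {latent.shape[0]} rows but {modality!r} observes "
            f"{int(observed.sum())} patients"
        )
    if latent.shape[0] == 0:
        raise ValueError(f"modality {modality!r} observes no patients")
    full = np.empty((manifest.n_patients, latent.shape[1]))
    full[observed] = latent
    full[~observed] = np.median(latent, axis=0)
    return full


def pool_shared_latent(latents, projections) -> np.ndarray:
    """Mean-pool per-modality projected latents into the node feature matrix.

    X = mean_m(latent_m @ W_m + b_m); all latents must already be
    union-sized (post-imputation).
    """
    latents = list(latents)
    n_rows = {z.shape[0] for z in latents}
    if len(n_rows) != 1:
        raise ValueError(f"latents disagree on patient count: {sorted(n_rows)}")
    projected = [z @ W + b for z, (W, b) in zip(latents, projections)]
    return np.mean(projected, axis=0)


def normalized_laplacian(A: np.ndarray) -> np.ndarray:
    """Symmetric-normalized propagation matrix L = D̃^(-1/2) Ã D̃^(-1/2).

    Ã = A + I adds self-loops; D̃ is the degree matrix of Ã. With no
    edges, L is the identity.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    At = A + np.eye(A.shape[0])
    d = At.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return At * inv_sqrt[:, None] * inv_sqrt[None, :]


def gcn_forward(X: np.ndarray, L: np.ndarray, weights: dict,
                bn: dict | None = None) -> np.ndarray:
    """Standalone two-layer GCN forward pass (evaluation mode).

    logits = L · bn(relu(L · X · W0 + b0)) · W1 + b1, with the optional
    batch-norm ``bn`` supplying gamma/beta/mean/var. Raises on non-finite
    intermediate values, naming the offending layer.
    """
    h = L @ np.asarray(X, dtype=float) @ weights["W0"] + weights["b0"]
    h = np.maximum(h, 0.0)
    if bn is not None:
        h = bn["gamma"] * (h - bn["mean"]) / np.sqrt(bn["var"] + _BN_EPS) + bn["beta"]
    if not np.isfinite(h).all():
        raise FloatingPointError("non-finite values in GCN layer 1")
    with np.errstate(invalid="ignore"):
        logits = L @ h @ weights["W1"] + weights["b1"]
    if not np.isfinite(logits).all():
        raise FloatingPointError("non-finite values in GCN layer 2")
    return logits


def masked_cross_entropy(logits: np.ndarray, y: np.ndarray, mask: np.ndarray) -> float:
    """Mean softmax cross-entropy over masked nodes only."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no nodes")
    z = logits[mask]
    z = z - z.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-logp[np.arange(z.shape[0]), np.asarray(y)[mask]].mean())


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _glorot(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


# ---------------------------------------------------------------------------
# The jointly trained model


class GcnMme:
    """Per-modality encoders + shared latent pooling + two-layer GCN.

    Parameters
    ----------
    encoder_specs : list of EncoderSpec
        One per modality, in pipeline order.
    shared_dim : int
        Dimension d of the pooled node feature matrix.
    gcn_hidden : int
        Width of the first graph convolution.
    n_classes : int
        Output dimension of the second graph convolution.
    batch_norm : bool
        Batch-normalize the first GCN layer's activations. Automatically
        disabled for graphs with fewer than 8 nodes, where batch statistics
        degenerate.
    seed : int
        Governs weight initialization; training itself is deterministic.
    """

    def __init__(self, encoder_specs, shared_dim: int, gcn_hidden: int,
                 n_classes: int, batch_norm: bool = True, seed: int = 0):
        self.specs = list(encoder_specs)
        self.shared_dim = int(shared_dim)
        self.gcn_hidden = int(gcn_hidden)
        self.n_classes = int(n_classes)
        self.batch_norm = bool(batch_norm)
        self.seed = int(seed)
        self.trained = False
        self.history = None
        rng = np.random.default_rng(seed)
        p = {}
        for s in self.specs:
            m = s.modality_name
            p[f"{m}/W1"] = _glorot(rng, s.input_dim, s.hidden_dim)
            p[f"{m}/b1"] = np.zeros(s.hidden_dim)
            p[f"{m}/W2"] = _glorot(rng, s.hidden_dim, s.latent_dim)
            p[f"{m}/b2"] = np.zeros(s.latent_dim)
            p[f"{m}/W3"] = _glorot(rng, s.latent_dim, shared_dim)
            p[f"{m}/b3"] = np.zeros(shared_dim)
        p["gcn/W0"] = _glorot(rng, shared_dim, gcn_hidden)
        p["gcn/b0"] = np.zeros(gcn_hidden)
        p["gcn/gamma"] = np.ones(gcn_hidden)
        p["gcn/beta"] = np.zeros(gcn_hidden)
        p["gcn/W1"] = _glorot(rng, gcn_hidden, n_classes)
        p["gcn/b1"] = np.zeros(n_classes)
        self.params = p
        self.bn_running_mean = np.zeros(gcn_hidden)
        self.bn_running_var = np.ones(gcn_hidden)

    # -- data preparation ---------------------------------------------------

    @staticmethod
    def prepare_inputs(matrices, manifest: SampleManifest):
        """Standardize each modality and align rows to the manifest.

        Returns per-modality (values, observed_flags) with features scaled
        to zero mean / unit variance over observed patients — the encoders
        expect roughly standardized inputs regardless of data kind.
        """
        prepared = []
        for m in matrices:
            if m.missing_mask.any():
                raise ValueError(f"{m.modality_name}: matrix must be complete")
            obs_ids = manifest.observed_ids(m.modality_name)
            sub = m.select_samples(obs_ids)
            x = sub.values
            mu, sd = x.mean(axis=0), x.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            prepared.append(((x - mu) / sd,
                             manifest.observed[m.modality_name].to_numpy()))
        return prepared

    # -- forward / backward -------------------------------------------------

    def _use_bn(self, n: int) -> bool:
        return self.batch_norm and n >= 8

    def forward(self, inputs, L: np.ndarray, train: bool = False):
        """Full forward pass; returns (logits, cache) over all union nodes.

        ``inputs`` is the output of :meth:`prepare_inputs`. In train mode
        batch-norm uses batch statistics (updating running averages);
        otherwise the stored running statistics.
        """
        p = self.params
        n = L.shape[0]
        cache = {"per_mod": [], "n": n}
        projected = []
        for s, (x, observed) in zip(self.specs, inputs):
            m = s.modality_name
            a1 = x @ p[f"{m}/W1"] + p[f"{m}/b1"]
            z1 = np.maximum(a1, 0.0)
            lat = z1 @ p[f"{m}/W2"] + p[f"{m}/b2"]
            full = np.empty((n, s.latent_dim))
            full[observed] = lat
            if (~observed).any():
                # median imputation: recomputed each pass, constant w.r.t. grads
                full[~observed] = np.median(lat, axis=0)
            proj = full @ p[f"{m}/W3"] + p[f"{m}/b3"]
            projected.append(proj)
            cache["per_mod"].append({"x": x, "a1": a1, "z1": z1, "full": full,
                                     "observed": observed})
        X = np.mean(projected, axis=0)
        M1 = L @ X
        a2 = M1 @ p["gcn/W0"] + p["gcn/b0"]
        r2 = np.maximum(a2, 0.0)
        if self._use_bn(n):
            if train:
                mu = r2.mean(axis=0)
                var = r2.var(axis=0)
                self.bn_running_mean = ((1 - _BN_MOMENTUM) * self.bn_running_mean
                                        + _BN_MOMENTUM * mu)
                self.bn_running_var = ((1 - _BN_MOMENTUM) * self.bn_running_var
                                       + _BN_MOMENTUM * var)
            else:
                mu, var = self.bn_running_mean, self.bn_running_var
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (r2 - mu) * inv_std
            h1 = p["gcn/gamma"] * xhat + p["gcn/beta"]
            cache.update(bn=True, bn_train=train, xhat=xhat, inv_std=inv_std, r2=r2)
        else:
            h1 = r2
            cache.update(bn=False)
        M2 = L @ h1
        logits = M2 @ p["gcn/W1"] + p["gcn/b1"]
        if not np.isfinite(logits).all():
            raise FloatingPointError("non-finite values in GCN output layer")
        cache.update(X=X, M1=M1, a2=a2, M2=M2, L=L)
        return logits, cache

    def backward(self, logits, cache, y: np.ndarray, mask: np.ndarray) -> dict:
        """Gradients of the masked cross-entropy w.r.t. every parameter."""
        p = self.params
        n = cache["n"]
        n_masked = int(mask.sum())
        probs = _softmax(logits)
        dlogits = np.zeros_like(logits)
        onehot = np.zeros_like(logits)
        onehot[np.arange(n), np.asarray(y)] = 1.0
        dlogits[mask] = (probs[mask] - onehot[mask]) / n_masked

        g = {}
        L = cache["L"]
        g["gcn/W1"] = cache["M2"].T @ dlogits
        g["gcn/b1"] = dlogits.sum(axis=0)
        dM2 = dlogits @ p["gcn/W1"].T
        dh1 = L @ dM2  # L symmetric
        if cache["bn"]:
            xhat, inv_std, r2 = cache["xhat"], cache["inv_std"], cache["r2"]
            g["gcn/gamma"] = (dh1 * xhat).sum(axis=0)
            g["gcn/beta"] = dh1.sum(axis=0)
            dxhat = dh1 * p["gcn/gamma"]
            if cache["bn_train"]:
                dr2 = (inv_std / n) * (n * dxhat - dxhat.sum(axis=0)
                                       - xhat * (dxhat * xhat).sum(axis=0))
            else:
                dr2 = dxhat * inv_std
        else:
            g["gcn/gamma"] = np.zeros_like(p["gcn/gamma"])
            g["gcn/beta"] = np.zeros_like(p["gcn/beta"])
            dr2 = dh1
        da2 = dr2 * (cache["a2"] > 0)
        g["gcn/W0"] = cache["M1"].T @ da2
        g["gcn/b0"] = da2.sum(axis=0)
        dM1 = da2 @ p["gcn/W0"].T
        dX = L @ dM1
        dproj = dX / len(self.specs)
        for s, mc in zip(self.specs, cache["per_mod"]):
            m = s.modality_name
            g[f"{m}/W3"] = mc["full"].T @ dproj
            g[f"{m}/b3"] = dproj.sum(axis=0)
            dfull = dproj @ p[f"{m}/W3"].T
            dlat = dfull[mc["observed"]]  # imputed rows are constants
            g[f"{m}/W2"] = mc["z1"].T @ dlat
            g[f"{m}/b2"] = dlat.sum(axis=0)
            dz1 = dlat @ p[f"{m}/W2"].T
            da1 = dz1 * (mc["a1"] > 0)
            g[f"{m}/W1"] = mc["x"].T @ da1
            g[f"{m}/b1"] = da1.sum(axis=0)
        return g

    # -- training -----------------------------------------------------------

    def fit(self, inputs, graph: PatientGraph, y: np.ndarray, masks: Masks,
            learning_rate: float = 1e-3, weight_decay: float = 5e-4,
            max_epochs: int = 500, patience: int = 50) -> "GcnMme":
        """Jointly train encoders, projections and GCN by Adam.

        Early stopping monitors the validation-mask loss; the parameters
        from the best validation epoch are restored. Training-node labels
        are the only labels ever read: validation labels steer stopping,
        test labels are untouched.
        """
        L = normalized_laplacian(graph.adjacency)
        y = np.asarray(y, dtype=int)
        if not masks.train.any():
            raise ValueError("training mask selects no nodes")
        decayed = {k for k in self.params if "/W" in k}
        m_state = {k: np.zeros_like(v) for k, v in self.params.items()}
        v_state = {k: np.zeros_like(v) for k, v in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        history = {"epoch": [], "train_loss": [], "val_loss": []}
        best_val = np.inf
        best_state = None
        wait = 0
        has_val = bool(masks.val.any())
        for epoch in range(1, max_epochs + 1):
            logits, cache = self.forward(inputs, L, train=True)
            train_loss = masked_cross_entropy(logits, y, masks.train)
            if not np.isfinite(train_loss):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            val_loss = (masked_cross_entropy(logits, y, masks.val)
                        if has_val else train_loss)
            grads = self.backward(logits, cache, y, masks.train)
            for k in self.params:
                gk = grads[k]
                if k in decayed:
                    gk = gk + weight_decay * self.params[k]
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * gk
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * gk * gk
                mhat = m_state[k] / (1 - beta1 ** epoch)
                vhat = v_state[k] / (1 - beta2 ** epoch)
                self.params[k] = self.params[k] - learning_rate * mhat / (np.sqrt(vhat) + eps)
            history["epoch"].append(epoch)
            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = ({k: v.copy() for k, v in self.params.items()},
                              self.bn_running_mean.copy(), self.bn_running_var.copy())
                wait = 0
            else:
                wait += 1
                if wait >= patience:
                    break
        if best_state is not None:
            self.params, self.bn_running_mean, self.bn_running_var = (
                {k: v.copy() for k, v in best_state[0].items()},
                best_state[1], best_state[2])
        self.history = history
        self.trained = True
        return self

    def predict(self, inputs, graph: PatientGraph):
        """Class code and class probabilities for every union patient.

        Evaluation-mode forward pass (batch norm uses running statistics);
        patients missing from modalities are covered by median imputation
        and receive predictions like everyone else.
        """
        if not self.trained:
            raise RuntimeError("model has not been trained; call fit() first")
        L = normalized_laplacian(graph.adjacency)
        logits, _ = self.forward(inputs, L, train=False)
        probs = _softmax(logits)
        return probs.argmax(axis=1), probs


def build_model(matrices, manifest: SampleManifest, labels: LabelSet, config) -> GcnMme:
    """Construct a GcnMme sized for the given matrices and RunConfig.

    Per-modality latent widths are capped at the modality's feature count
    so the encoder invariant input_dim >= latent_dim always holds.
    """
    specs = [
        EncoderSpec(m.modality_name, m.n_features,
                    hidden_dim=config.encoder_hidden,
                    latent_dim=min(config.latent_dim, m.n_features))
        for m in matrices
    ]
    return GcnMme(specs, config.shared_dim, config.gcn_hidden,
                  labels.n_classes, batch_norm=config.batch_norm,
                  seed=config.seed)
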