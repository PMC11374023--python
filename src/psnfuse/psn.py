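"""Patient similarity networks and similarity network fusion.

Each modality's selected features yield a patient x patient similarity
matrix (Pearson correlation where correlation is a suitable measure,
Euclidean distance otherwise). Per-modality networks are sparsified with
K nearest neighbours and fused into a single union-of-patients network by
SNF cross-diffusion, which reinforces relationships supported by several
modalities and dampens modality-specific noise. Patients absent from a
modality contribute no information to that modality's view; their
relationships are supplied by the modalities that do observe them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import OmicsMatrix, PatientGraph, SampleManifest
from .io import SNFConfig

_EPS = 1e-20


@dataclass
class SimilarityMatrix:
    """Dense symmetric patient x patient similarity (or distance) matrix.

    ``metric`` records the semantics: for ``"pearson"`` larger is more
    similar (diagonal 1); for ``"euclidean"`` the entries are distances,
    smaller is more similar (diagonal 0). Consumers must respect the flag.
    """

    patient_ids: list
    S: np.ndarray
    metric: str

    def __post_init__(self):
        self.patient_ids = list(self.patient_ids)
        if self.metric not in ("pearson", "euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.patient_ids)
        if self.S.shape != (n, n):
            raise ValueError("S must be square over patient_ids")
        if not np.allclose(self.S, self.S.T, atol=1e-12):
            raise ValueError("S must be symmetric")

    @property
    def n(self) -> int:
        return len(self.patient_ids)


@dataclass
class AffinityMatrix:
    """Non-negative symmetric affinity over the union patient list.

    ``observed`` flags which union patients this modality measured;
    entries where either patient is unobserved are zero, and
    ``observed_pair_mask`` is the outer product of the flags.
    """

    patient_ids: list
    W: np.ndarray
    observed: np.ndarray

    def __post_init__(self):
        self.patient_ids = list(self.patient_ids)
        self.W = np.asarray(self.W, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        n = len(self.patient_ids)
        if self.W.shape != (n, n) or self.observed.shape != (n,):
            raise ValueError("W / observed shapes inconsistent with patient_ids")
        if (self.W < 0).any():
            raise ValueError("affinities must be non-negative")
        if not np.allclose(self.W, self.W.T, atol=1e-12):
            raise ValueError("W must be symmetric")
        if self.W[~self.observed_pair_mask].any():
            raise ValueError("W must be zero outside the observed block")

    @property
    def observed_pair_mask(self) -> np.ndarray:
        return np.outer(self.observed, self.observed)

    @property
    def n(self) -> int:
        return len(self.patient_ids)


def pearson_similarity(m, sample_ids=None) -> SimilarityMatrix:
    """Patient x patient Pearson correlation across selected features.

    r(x, y) = sum((x_i - x̄)(y_i - ȳ)) / sqrt(sum((x_i - x̄)^2) sum((y_i - ȳ)^2))
    computed between every pair of sample rows. Diagonal is 1.
    """
    x, ids = _as_array(m, sample_ids)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 features per sample for correlation")
    sdev = x.std(axis=1)
    if (sdev == 0).any():
        bad = ids[int(np.argmax(sdev == 0))]
        raise ValueError(f"sample {bad!r} has zero variance across features")
    S = np.corrcoef(x)
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2
    return SimilarityMatrix(ids, S, "pearson")


def euclidean_distance(m, sample_ids=None) -> SimilarityMatrix:
    """Pairwise Euclidean distance r(p, q) = sqrt(sum_i (q_i - p_i)^2)."""
    x, ids = _as_array(m, sample_ids)
    from scipy.spatial.distance import squareform, pdist
    S = squareform(pdist(x, metric="euclidean"))
    return SimilarityMatrix(ids, S, "euclidean")


def similarity(m, metric: str, sample_ids=None) -> SimilarityMatrix:
    if metric == "pearson":
        return pearson_similarity(m, sample_ids)
    if metric == "euclidean":
        return euclidean_distance(m, sample_ids)
    raise ValueError(f"unknown metric {metric!r}")


def _as_array(m, sample_ids):
    if isinstance(m, OmicsMatrix):
        if m.missing_mask.any():
            raise ValueError("matrix must be complete for similarity computation")
        return m.values, list(m.sample_ids)
    x = np.asarray(m, dtype=float)
    if np.isnan(x).any():
        raise ValueError("matrix must be complete for similarity computation")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(x.shape[0])]
    if len(sample_ids) != x.shape[0]:
        raise ValueError("sample_ids length does not match row count")
    return x, list(sample_ids)


def _neighbour_order(sim: SimilarityMatrix) -> np.ndarray:
    """Per-row candidate ordering, most similar first, ties by patient ID."""
    n = sim.n
    key = -sim.S if sim.metric == "pearson" else sim.S.copy()
    # lexsort: primary key similarity, secondary patient ID for determinism
    id_rank = np.argsort(np.argsort(sim.patient_ids))
    order = np.empty((n, n - 1), dtype=int)
    for i in range(n):
        cand = np.array([j for j in range(n) if j != i])
        order[i] = cand[np.lexsort((id_rank[cand], key[i, cand]))]
    return order


def knn_graph(sim: SimilarityMatrix, k: int, mutual: bool = False) -> PatientGraph:
    """K-nearest-neighbour sparsification of a similarity matrix.

    Each patient selects its k most similar others (descending Pearson
    similarity or ascending Euclidean distance; ties broken by patient
    ID). Edges are symmetrized by union — an edge exists if either
    endpoint selected the other — or by intersection when ``mutual``.
    Edge weights are the similarity for Pearson (floored at a tiny
    positive value so a selected edge is never dropped) and 1 / (1 + d)
    for Euclidean distance.
    """
    n = sim.n
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the number of patients ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    order = _neighbour_order(sim)
    selects = np.zeros((n, n), dtype=bool)
    for i in range(n):
        selects[i, order[i, :k]] = True
    keep = (selects & selects.T) if mutual else (selects | selects.T)
    if sim.metric == "pearson":
        weight = np.maximum(sim.S, _EPS)
    else:
        weight = 1.0 / (1.0 + sim.S)
    w = np.where(keep, weight, 0.0)
    np.fill_diagonal(w, 0.0)
    return PatientGraph(sim.patient_ids, (w + w.T) / 2)


def _distance_matrix(sim: SimilarityMatrix) -> np.ndarray:
    """Distance view of a similarity matrix: 1 - r for Pearson, d as-is."""
    if sim.metric == "pearson":
        d = 1.0 - sim.S
    else:
        d = sim.S.copy()
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def make_affinity(sim: SimilarityMatrix, manifest: SampleManifest | None = None,
                  cfg: SNFConfig | None = None) -> AffinityMatrix:
    """Scaled exponential kernel affinity from a similarity matrix.

    W[i, j] = exp(-d(i, j)^2 / (mu * eps_ij)) with
    eps_ij = (mean_k d(i, nn_k(i)) + mean_k d(j, nn_k(j)) + d(i, j)) / 3,
    where nn_k ranges over each point's K nearest neighbours (self
    excluded). When a manifest is given, the kernel is embedded into the
    union patient list with zeros for unobserved pairs.
    """
    cfg = cfg or SNFConfig()
    n = sim.n
    if cfg.K >= n:
        raise ValueError(f"kernel K = {cfg.K} must be smaller than n observed ({n})")
    d = _distance_matrix(sim)
    sorted_d = np.sort(d, axis=1)
    mean_knn = sorted_d[:, 1:cfg.K + 1].mean(axis=1)  # column 0 is self (0)
    eps = (mean_knn[:, None] + mean_knn[None, :] + d) / 3.0
    eps = np.maximum(eps, _EPS)
    W = np.exp(-(d ** 2) / (cfg.mu * eps))
    W = (W + W.T) / 2
    if manifest is None:
        return AffinityMatrix(sim.patient_ids, W, np.ones(n, dtype=bool))
    union = manifest.union_ids
    pos = {p: i for i, p in enumerate(union)}
    idx = np.array([pos[p] for p in sim.patient_ids])
    observed = np.zeros(len(union), dtype=bool)
    observed[idx] = True
    Wu = np.zeros((len(union), len(union)))
    Wu[np.ix_(idx, idx)] = W
    return AffinityMatrix(union, Wu, observed)


def _full_normalize(W: np.ndarray) -> np.ndarray:
    """Row normalization that caps the diagonal mass at 1/2.

    P[i, j] = W[i, j] / (2 * sum_{k != i} W[i, k]) off-diagonal, P[i, i] = 1/2.
    This keeps the transition matrix stable regardless of the diagonal of W.
    """
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rs = off.sum(axis=1)
    P = np.zeros_like(W)
    pos = rs > 0
    P[pos] = off[pos] / (2.0 * rs[pos, None])
    np.fill_diagonal(P, 0.5)
    return P


def _local_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """K-NN restricted row-stochastic kernel (self excluded)."""
    n = W.shape[0]
    K = min(K, n - 1)
    off = W.copy()
    np.fill_diagonal(off, -np.inf)
    S = np.zeros_like(W)
    for i in range(n):
        nn = np.argsort(-off[i], kind="stable")[:K]
        mass = W[i, nn].sum()
        if mass > 0:
            S[i, nn] = W[i, nn] / mass
    return S


def snf_fuse(affinities, cfg: SNFConfig | None = None) -> AffinityMatrix:
    """Fuse per-modality affinities into one network by SNF cross-diffusion.

    Per modality v the full kernel P_v (row-normalized) and a K-NN local
    kernel S_v are formed; for T iterations P_v <- S_v M_v S_v^T where M_v
    is the elementwise mean of the other modalities' P matrices, followed
    by renormalization and symmetrization. The fused network is the
    elementwise mean of the final P_v.

    Patients missing from a modality: each modality diffuses on its own
    observed block; for a pair no other modality covers, the cross-modal
    mean falls back to the modality's own entry. Fused entries average
    only over modalities observing both patients and are zero for pairs
    covered by none. With full overlap this reduces exactly to standard
    SNF. With a single modality no diffusion is performed: the result is
    the row-normalized, symmetrized input.
    """
    cfg = cfg or SNFConfig()
    affinities = list(affinities)
    if not affinities:
        raise ValueError("need at least one affinity matrix")
    ids = affinities[0].patient_ids
    for a in affinities[1:]:
        if a.patient_ids != ids:
            raise ValueError("all affinities must share the same union patient list")
    cover = np.sum([a.observed_pair_mask for a in affinities], axis=0)
    uncovered_patients = ~np.logical_or.reduce([a.observed for a in affinities])
    if uncovered_patients.any():
        bad = ids[int(np.argmax(uncovered_patients))]
        raise ValueError(f"patient {bad!r} is observed in no modality")

    n_union = len(ids)
    blocks = []
    for a in affinities:
        idx = np.where(a.observed)[0]
        Wv = a.W[np.ix_(idx, idx)]
        P = _full_normalize(Wv)
        P = (P + P.T) / 2
        S = _local_kernel(Wv, min(cfg.K, len(idx) - 1) if len(idx) > 1 else 1)
        blocks.append({"idx": idx, "P": P, "S": S, "obs": a.observed})

    if len(blocks) > 1:
        for _ in range(cfg.T):
            embedded = []
            for b in blocks:
                E = np.zeros((n_union, n_union))
                E[np.ix_(b["idx"], b["idx"])] = b["P"]
                embedded.append(E)
            masks = [a.observed_pair_mask for a in affinities]
            new_P = []
            for v, b in enumerate(blocks):
                ix = np.ix_(b["idx"], b["idx"])
                num = np.zeros((len(b["idx"]),) * 2)
                den = np.zeros_like(num)
                for w in range(len(blocks)):
                    if w == v:
                        continue
                    num += np.where(masks[w][ix], embedded[w][ix], 0.0)
                    den += masks[w][ix]
                M = np.where(den > 0, num / np.maximum(den, 1), b["P"])
                P = b["S"] @ M @ b["S"].T
                P = _full_normalize(P)
                new_P.append((P + P.T) / 2)
            for b, P in zip(blocks, new_P):
                b["P"] = P

    num = np.zeros((n_union, n_union))
    for a, b in zip(affinities, blocks):
        E = np.zeros((n_union, n_union))
        E[np.ix_(b["idx"], b["idx"])] = b["P"]
        num += np.where(a.observed_pair_mask, E, 0.0)
    fused = np.where(cover > 0, num / np.maximum(cover, 1), 0.0)
    fused = (fused + fused.T) / 2
    observed = np.logical_or.reduce([a.observed for a in affinities])
    return AffinityMatrix(ids, fused, observed)


def fused_to_graph(fused: AffinityMatrix, k: int, mutual: bool = False) -> PatientGraph:
    """KNN sparsification of the fused network into the final patient graph.

    Every union patient appears as a node, including patients missing from
    some modalities. The graph keeps the fused affinities as edge weights
    for reporting; the binary ``adjacency`` view is what the GCN consumes.
    """
    S = fused.W.copy()
    np.fill_diagonal(S, 0.0)
    sim = SimilarityMatrix(fused.patient_ids, S, "pearson")  # larger = more similar
    return knn_graph(sim, k, mutual=mutual)
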