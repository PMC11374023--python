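"""Readers and writers for every on-disk artifact.

Matrices and labels are delimited text (CSV or TSV, chosen by extension);
graphs are GraphML or a weighted edge-list; run configurations are YAML;
metrics reports are JSON. Missing entries are written as ``NA`` and read
from either an empty field or any capitalisation of ``NA``.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .containers import DATA_KINDS, LabelSet, OmicsMatrix, PatientGraph

NA_TOKENS = ["", "NA", "na", "Na", "nA"]
GRAPH_FORMATS = ("edge-list", "graphml")


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_omics_matrix(path, modality_name: str, data_kind: str) -> OmicsMatrix:
    """Read a samples x features delimited table.

    The header row holds feature IDs and the first column sample IDs.
    Empty cells or ``NA`` (any case) denote missing values. data_kind
    constraints (non-negative counts, beta in [0, 1]) are validated on
    observed entries.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                     keep_default_na=False, na_values=NA_TOKENS)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as e:
        raise ValueError(f"non-numeric cell in {path}: {e}") from None
    return OmicsMatrix(modality_name, list(df.index), list(df.columns), values, data_kind)


def write_omics_matrix(m: OmicsMatrix, path) -> None:
    m.to_frame().to_csv(path, sep=_sep_for(path), na_rep="NA", index_label="sample_id")


def read_labels(path) -> LabelSet:
    """Read a two-column sample_id,label table (header row required)."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str,
                     keep_default_na=False, na_values=NA_TOKENS)
    if df.shape[1] != 2:
        raise ValueError(f"label file must have exactly 2 columns, got {df.shape[1]}")
    sids, labels = df.iloc[:, 0], df.iloc[:, 1]
    bad = sids[labels.isna() | sids.isna()]
    if len(bad):
        raise ValueError(f"sample with missing label: {bad.iloc[0]!r}")
    return LabelSet(list(sids), list(labels))


def write_labels(labels: LabelSet, path) -> None:
    pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.classes}).to_csv(
        path, sep=_sep_for(path), index=False)


def write_graph(graph: PatientGraph, path, format: str = "graphml") -> None:
    """Write a patient graph; node IDs and edge weights are preserved.

    ``edge-list`` writes one ``u<TAB>v<TAB>weight`` line per edge plus a
    single-field line per isolated node so that degree-0 patients survive
    the round trip. ``graphml`` uses networkx GraphML with full-precision
    weights.
    """
    fmt = format.lower()
    if fmt not in GRAPH_FORMATS:
        raise ValueError(f"unknown graph format {format!r}; expected one of {GRAPH_FORMATS}")
    g = to_networkx(graph)
    if fmt == "graphml":
        # GraphML stores doubles; repr round-trips float64 exactly
        nx.write_graphml(g, path)
    else:
        with open(path, "w") as fh:
            for u, v, w in graph.edges():
                fh.write(f"{u}\t{v}\t{w!r}\n")
            for node, deg in zip(graph.patient_ids, graph.degree()):
                if deg == 0:
                    fh.write(f"{node}\n")


def read_graph(path, format: str = "graphml") -> PatientGraph:
    fmt = format.lower()
    if fmt not in GRAPH_FORMATS:
        raise ValueError(f"unknown graph format {format!r}; expected one of {GRAPH_FORMATS}")
    if fmt == "graphml":
        g = nx.read_graphml(path)
        return from_networkx(g)
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1 and parts[0]:
                g.add_node(parts[0])
            elif len(parts) == 3:
                g.add_edge(parts[0], parts[1], weight=float(parts[2]))
            elif any(parts):
                raise ValueError(f"malformed edge-list line: {line!r}")
    return from_networkx(g)


def to_networkx(graph: PatientGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(graph.patient_ids)
    g.add_weighted_edges_from(graph.edges())
    return g


def from_networkx(g: nx.Graph) -> PatientGraph:
    ids = sorted(g.nodes)
    idx = {p: i for i, p in enumerate(ids)}
    w = np.zeros((len(ids), len(ids)))
    for u, v, data in g.edges(data=True):
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = data.get("weight", 1.0)
    return PatientGraph(ids, w)


def write_metrics(report, path) -> None:
    """Serialize a metrics report (dataclass or dict) as JSON."""
    if dataclasses.is_dataclass(report) and not isinstance(report, type):
        report = dataclasses.asdict(report)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=default)
        fh.write("\n")


def read_metrics(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class ModalityConfig:
    """Per-modality settings: data kind, feature-selection route, transforms."""

    name: str
    data_kind: str
    feature_selection: str = "auto"  # auto -> de for counts, elastic_net otherwise
    log_transform: bool = False

    def __post_init__(self):
        if self.data_kind not in DATA_KINDS:
            raise ValueError(f"unknown data_kind {self.data_kind!r}")
        if self.feature_selection not in ("auto", "de", "elastic_net", "none"):
            raise ValueError(f"unknown feature_selection {self.feature_selection!r}")

    @property
    def resolved_selection(self) -> str:
        if self.feature_selection != "auto":
            return self.feature_selection
        return "de" if self.data_kind == "counts" else "elastic_net"


@dataclass
class SNFConfig:
    """Similarity-network-fusion hyperparameters.

    K is the kernel / local-neighbourhood size, mu scales the kernel
    bandwidth, T is the number of cross-diffusion iterations.
    """

    K: int = 20
    mu: float = 0.5
    T: int = 20

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.T < 1:
            raise ValueError("T must be >= 1")


@dataclass
class RunConfig:
    """Everything one run needs: modality plan, graph, model and training knobs."""

    modalities: list = field(default_factory=list)
    k_neighbours: int = 15
    snf: SNFConfig = field(default_factory=SNFConfig)
    mutual_knn: bool = False
    weighted_adjacency: bool = False
    encoder_hidden: int = 500
    latent_dim: int = 32
    shared_dim: int = 32
    gcn_hidden: int = 64
    batch_norm: bool = True
    learning_rate: float = 1e-3
    weight_decay: float = 5e-4
    max_epochs: int = 500
    patience: int = 50
    n_folds: int = 5
    val_frac: float = 0.15
    de_alpha: float = 0.05
    missingness_threshold: float = 0.5
    outlier_sd: float = 2.0
    elastic_net_mixing: float = 0.5
    per_fold_selection: bool = False
    seed: int = 0

    def __post_init__(self):
        self.modalities = [
            m if isinstance(m, ModalityConfig) else ModalityConfig(**m)
            for m in self.modalities
        ]
        if isinstance(self.snf, dict):
            self.snf = SNFConfig(**self.snf)
        if self.k_neighbours < 1:
            raise ValueError("k_neighbours must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        for name in ("encoder_hidden", "latent_dim", "shared_dim", "gcn_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def read_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def write_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)
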