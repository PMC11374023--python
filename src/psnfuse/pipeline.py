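"""End-to-end driver: preprocess modalities, build the fused network,
train and evaluate the GCN-MME.

Count modalities run the differential-expression route (uninformative-
feature filter, median-of-ratios normalization, connectivity outlier
removal, one-vs-rest DE); other modalities run the penalized route
(missingness filter with mean imputation, optional log transform,
elastic-net selection). Patient similarity uses Pearson correlation for
counts and beta-values and Euclidean distance for continuous modalities,
where correlation across heterogeneous scales is less meaningful.

By default feature selection and the fused graph are computed once over
all patients before cross-validation — the transductive protocol, which
trades a known information bias for a single shared network. A strict
mode (``per_fold_selection``) instead re-runs supervised selection inside
each fold on that fold's train + validation patients only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import LabelSet, OmicsMatrix, PatientGraph, SampleManifest, build_manifest
from .evaluate import CrossValReport, _run_folds, cross_validate, make_splits
from .io import ModalityConfig, RunConfig, SNFConfig
from .preprocess import (FeatureSelectionResult, de_one_vs_rest, elastic_net_select,
                         filter_missingness, filter_uninformative_features,
                         log_transform, normalize_counts, remove_outlier_samples)
from .psn import AffinityMatrix, fused_to_graph, make_affinity, similarity, snf_fuse


def metric_for(data_kind: str) -> str:
    return "euclidean" if data_kind == "continuous" else "pearson"


def _suitable_metric(m: OmicsMatrix) -> str:
    """Pearson where suitable, otherwise Euclidean.

    Correlation is unsuitable when a sample is constant across the
    selected features or when fewer than 3 features survive selection
    (two-point correlations are degenerate).
    """
    metric = metric_for(m.data_kind)
    if metric == "pearson":
        if m.n_features < 3 or (m.values.std(axis=1) == 0).any():
            return "euclidean"
    return metric


@dataclass
class PreparedModality:
    """One modality after unsupervised preparation and feature selection."""

    matrix: OmicsMatrix                    # complete, selected features, model-ready
    base: OmicsMatrix                      # complete, all surviving features
    selection: FeatureSelectionResult | None
    removed_samples: list


def _prepare_base(matrix: OmicsMatrix, mcfg: ModalityConfig, cfg: RunConfig):
    """Unsupervised (label-free) preparation; shared by both CV modes."""
    removed = []
    if mcfg.data_kind == "counts":
        base = filter_uninformative_features(matrix)
        base, _ = normalize_counts(base)
        if base.n_samples >= 3:
            base, removed = remove_outlier_samples(base, cfg.outlier_sd)
    else:
        base = filter_missingness(matrix, cfg.missingness_threshold)
        if mcfg.log_transform:
            if mcfg.data_kind != "continuous":
                raise ValueError("log_transform applies to continuous modalities only")
            base, _ = log_transform(base)
    return base, removed


def _ranked_features(sel: FeatureSelectionResult) -> list:
    t = sel.table
    if sel.method == "de_one_vs_rest":
        ranked = (t.groupby("feature", sort=False)["adj_p"].min()
                  .reset_index().sort_values(["adj_p", "feature"]))
        return list(ranked["feature"])
    ranked = t.sort_values(["coef_magnitude", "feature"],
                           ascending=[False, True])
    return list(ranked["feature"])


def _select(base: OmicsMatrix, route: str, labels: LabelSet, cfg: RunConfig,
            fit_ids=None):
    """Supervised selection on ``fit_ids`` (or all samples); returns the
    model-ready matrix over the selected features of *all* base samples."""
    if route == "none":
        mat = base
        if base.data_kind == "counts":
            mat = base.replace_values(np.log2(base.values + 1.0))
        return mat, None
    if fit_ids is None:
        fit = base
    else:
        keep = [s for s in base.sample_ids if s in fit_ids]
        fit = base.select_samples(keep)
    if route == "de":
        sel = de_one_vs_rest(fit, labels, cfg.de_alpha)
    elif route == "elastic_net":
        sel = elastic_net_select(fit, labels, cfg.elastic_net_mixing, seed=cfg.seed)
    else:
        raise ValueError(f"unknown feature-selection route {route!r}")
    feats = sel.selected_feature_ids
    if len(feats) < 2:
        # similarity needs >= 2 features; keep the 2 top-ranked ones
        feats = _ranked_features(sel)[:2]
    sub = base.select_features(feats)
    if base.data_kind == "counts":
        sub = sub.replace_values(np.log2(sub.values + 1.0))
    return sub, sel


def prepare_modality(matrix: OmicsMatrix, labels: LabelSet, mcfg: ModalityConfig,
                     cfg: RunConfig, fit_ids=None) -> PreparedModality:
    """Full preprocessing of one modality: cleaning then feature selection."""
    base, removed = _prepare_base(matrix, mcfg, cfg)
    mat, sel = _select(base, mcfg.resolved_selection, labels, cfg, fit_ids=fit_ids)
    return PreparedModality(mat, base, sel, removed)


def build_network(matrices, cfg: RunConfig):
    """Per-modality PSNs -> SNF -> final KNN patient graph.

    Returns (PatientGraph, fused AffinityMatrix, SampleManifest). The SNF
    kernel K and the final k are capped below each modality's observed
    count / the union size so small cohorts remain valid inputs.
    """
    matrices = list(matrices)
    manifest = build_manifest(matrices)
    affinities = []
    for m in matrices:
        sim = similarity(m, _suitable_metric(m))
        K = min(cfg.snf.K, m.n_samples - 1)
        local = SNFConfig(K=K, mu=cfg.snf.mu, T=cfg.snf.T)
        affinities.append(make_affinity(sim, manifest, local))
    fused = snf_fuse(affinities, cfg.snf)
    k = min(cfg.k_neighbours, manifest.n_patients - 1)
    graph = fused_to_graph(fused, k, mutual=cfg.mutual_knn)
    return graph, fused, manifest


@dataclass
class PipelineResult:
    """Everything one run produces, from selection tables to CV metrics."""

    prepared: list
    manifest: SampleManifest
    fused: AffinityMatrix
    graph: PatientGraph
    cv: CrossValReport


def run_pipeline(raw_matrices, labels: LabelSet, cfg: RunConfig) -> PipelineResult:
    """Preprocess, build the fused network, and cross-validate."""
    raw_matrices = list(raw_matrices)
    mcfgs = _modality_configs(raw_matrices, cfg)
    if cfg.per_fold_selection:
        return _run_pipeline_strict(raw_matrices, labels, cfg, mcfgs)
    prepared = [prepare_modality(m, labels, mc, cfg)
                for m, mc in zip(raw_matrices, mcfgs)]
    mats = [p.matrix for p in prepared]
    graph, fused, manifest = build_network(mats, cfg)
    cv = cross_validate(mats, graph, manifest, labels, cfg)
    return PipelineResult(prepared, manifest, fused, graph, cv)


def _modality_configs(matrices, cfg: RunConfig):
    by_name = {mc.name: mc for mc in cfg.modalities}
    out = []
    for m in matrices:
        mc = by_name.get(m.modality_name)
        if mc is None:
            mc = ModalityConfig(m.modality_name, m.data_kind)
        elif mc.data_kind != m.data_kind:
            raise ValueError(
                f"config declares {m.modality_name!r} as {mc.data_kind}, "
                f"matrix says {m.data_kind}")
        out.append(mc)
    return out


def _run_pipeline_strict(raw_matrices, labels, cfg, mcfgs) -> PipelineResult:
    """Leakage-strict CV: supervised selection refit inside every fold."""
    bases = []
    for m, mc in zip(raw_matrices, mcfgs):
        base, removed = _prepare_base(m, mc, cfg)
        bases.append((base, mc, removed))
    manifest = build_manifest([b for b, _, _ in bases])
    union_labels = labels.subset(manifest.union_ids)
    splits = make_splits(union_labels, cfg.n_folds, cfg.val_frac, cfg.seed)
    fold_reports, last = [], None
    for split in splits:
        fit_ids = {p for p, keep in zip(manifest.union_ids,
                                        split.masks.train | split.masks.val) if keep}
        mats = []
        for base, mc, _ in bases:
            mat, _ = _select(base, mc.resolved_selection, labels, cfg, fit_ids=fit_ids)
            mats.append(mat)
        graph, fused, manifest_f = build_network(mats, cfg)
        results = _run_folds(mats, graph, manifest_f, labels, cfg, [split])
        fold_reports.append(results[0]["report"])
        last = (mats, graph, fused, manifest_f)
    accs = np.array([r.accuracy for r in fold_reports])
    f1s = np.array([r.weighted_f1 for r in fold_reports])
    cv = CrossValReport(fold_reports, float(accs.mean()), float(accs.std()),
                        float(f1s.mean()), float(f1s.std()))
    mats, graph, fused, manifest_f = last
    prepared = [PreparedModality(mat, base, None, removed)
                for mat, (base, _, removed) in zip(mats, bases)]
    return PipelineResult(prepared, manifest_f, fused, graph, cv)
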