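"""Cross-validated evaluation, ablation and hyperparameter search.

Evaluation follows the transductive protocol: the fused patient graph is
built once over all patients, then stratified k-fold splits (default 5)
divide the labelled patients into train / validation / test masks — with
the default 15% validation carve-out of the non-test patients this yields
a 68% / 12% / 20% split per fold. Models are trained per fold with early
stopping on the validation mask and scored on the test mask; accuracy and
class-size-weighted F1 are aggregated as mean +/- population SD over folds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import (accuracy_score, f1_score,
                             precision_recall_fscore_support, roc_auc_score)
from sklearn.model_selection import StratifiedKFold

from .containers import LabelSet, PatientGraph, SampleManifest
from .gcn import GcnMme, Masks, build_model
from .io import RunConfig


@dataclass
class SplitAssignment:
    """Train/validation/test masks for one cross-validation fold."""

    fold_id: int
    masks: Masks
    seed: int


@dataclass
class MetricsReport:
    """Metrics for one evaluation: accuracy, weighted F1, per-class detail."""

    accuracy: float
    weighted_f1: float
    per_class: dict
    n: int


@dataclass
class CrossValReport:
    """Per-fold metrics plus mean +/- SD (population SD over folds)."""

    folds: list
    accuracy_mean: float
    accuracy_sd: float
    f1_mean: float
    f1_sd: float
    val_accuracy_mean: float = float("nan")

    def summary(self) -> dict:
        return {
            "accuracy": {"mean": self.accuracy_mean, "sd": self.accuracy_sd},
            "weighted_f1": {"mean": self.f1_mean, "sd": self.f1_sd},
            "per_fold_accuracy": [f.accuracy for f in self.folds],
            "per_fold_weighted_f1": [f.weighted_f1 for f in self.folds],
        }


@dataclass
class AblationResult:
    """Cross-validated performance of one modality subset."""

    modalities: tuple
    report: CrossValReport
    n_patients: int


def make_splits(labels: LabelSet, n_folds: int = 5, val_frac_of_train: float = 0.15,
                seed: int = 0) -> list:
    """Stratified k-fold splits with a validation carve-out.

    The test folds partition the labelled patients (stratified by class).
    Within each fold, validation patients are drawn from the non-test
    patients, stratified per class with largest-remainder rounding so the
    validation set is as close as possible to ``val_frac_of_train`` of the
    non-test patients. Reproducible given the seed.
    """
    y = labels.codes_for(labels.sample_ids)
    counts = np.bincount(y, minlength=labels.n_classes)
    for c, cnt in zip(labels.class_names, counts):
        if cnt < n_folds:
            raise ValueError(f"class {c!r} has {cnt} members, fewer than {n_folds} folds")
    n = len(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = []
    for fold, (rest_idx, test_idx) in enumerate(skf.split(np.zeros(n), y)):
        rng = np.random.default_rng([seed, fold])
        n_val = int(round(val_frac_of_train * len(rest_idx)))
        rest_y = y[rest_idx]
        raw = np.array([val_frac_of_train * (rest_y == c).sum()
                        for c in range(labels.n_classes)])
        alloc = np.floor(raw).astype(int)
        short = n_val - alloc.sum()
        order = np.argsort(-(raw - alloc), kind="stable")
        for c in order[:max(short, 0)]:
            alloc[c] += 1
        val_idx = []
        for c in range(labels.n_classes):
            members = rest_idx[rest_y == c]
            take = min(alloc[c], len(members))
            if take:
                val_idx.extend(rng.choice(members, size=take, replace=False))
        val_idx = np.array(sorted(val_idx), dtype=int)
        train_mask = np.zeros(n, dtype=bool)
        val_mask = np.zeros(n, dtype=bool)
        test_mask = np.zeros(n, dtype=bool)
        test_mask[test_idx] = True
        val_mask[val_idx] = True
        train_mask[rest_idx] = True
        train_mask[val_idx] = False
        splits.append(SplitAssignment(fold, Masks(train_mask, val_mask, test_mask), seed))
    return splits


def compute_metrics(y_true, y_pred, probabilities=None, class_names=None) -> MetricsReport:
    """Accuracy, per-class precision/recall/F1/AUC and weighted F1.

    ``y_true`` / ``y_pred`` are integer class codes into ``class_names``;
    ``probabilities`` (optional, rows summing to 1) enables one-vs-rest
    AUC per class.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if class_names is None:
        class_names = [f"C{k}" for k in range(int(max(y_true.max(), y_pred.max())) + 1)]
    n_classes = len(class_names)
    if y_pred.min() < 0 or y_pred.max() >= n_classes:
        raise ValueError(f"prediction code {int(y_pred.max())} outside known classes")
    if probabilities is not None:
        probabilities = np.asarray(probabilities, dtype=float)
        if probabilities.shape != (len(y_true), n_classes):
            raise ValueError("probabilities shape mismatch")
        if not np.allclose(probabilities.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
    acc = accuracy_score(y_true, y_pred)
    labels_range = list(range(n_classes))
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels_range, zero_division=0)
    wf1 = f1_score(y_true, y_pred, labels=labels_range, average="weighted",
                   zero_division=0)
    per_class = {}
    for k, name in enumerate(class_names):
        auc = float("nan")
        if probabilities is not None:
            pos = y_true == k
            if pos.any() and (~pos).any():
                auc = float(roc_auc_score(pos, probabilities[:, k]))
        per_class[name] = {
            "precision": float(prec[k]), "recall": float(rec[k]),
            "f1": float(f1[k]), "support": int(support[k]), "auc": auc,
        }
    return MetricsReport(float(acc), float(wf1), per_class, int(len(y_true)))


def plot_roc_curves(y_true, probabilities, class_names, path):
    """One-vs-rest ROC curve per class, written as an image file.

    Requires matplotlib (optional dependency); raises ImportError with a
    hint when it is absent.
    """
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as e:  # pragma: no cover
        raise ImportError("ROC plotting requires matplotlib "
                          "(pip install psnfuse[plot])") from e
    from sklearn.metrics import roc_curve
    y_true = np.asarray(y_true, dtype=int)
    probabilities = np.asarray(probabilities, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    for k, name in enumerate(class_names):
        pos = y_true == k
        if not pos.any() or pos.all():
            continue
        fpr, tpr, _ = roc_curve(pos, probabilities[:, k])
        auc = float(roc_auc_score(pos, probabilities[:, k]))
        ax.plot(fpr, tpr, label=f"{name} (AUC {auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _run_folds(matrices, graph: PatientGraph, manifest: SampleManifest,
               labels: LabelSet, config: RunConfig, splits):
    """Train and score one model per fold; shared by CV and the search."""
    y = labels.codes_for(manifest.union_ids)
    inputs = GcnMme.prepare_inputs(matrices, manifest)
    out = []
    for split in splits:
        model = build_model(matrices, manifest, labels,
                            replace(config, seed=config.seed + split.fold_id))
        model.fit(inputs, graph, y, split.masks,
                  learning_rate=config.learning_rate,
                  weight_decay=config.weight_decay,
                  max_epochs=config.max_epochs, patience=config.patience)
        pred, probs = model.predict(inputs, graph)
        t = split.masks.test
        report = compute_metrics(y[t], pred[t], probs[t], labels.class_names)
        v = split.masks.val
        val_acc = float(accuracy_score(y[v], pred[v])) if v.any() else float("nan")
        out.append({"fold": split.fold_id, "report": report,
                    "val_accuracy": val_acc, "model": model})
    return out


def cross_validate(matrices, graph: PatientGraph, manifest: SampleManifest,
                   labels: LabelSet, config: RunConfig,
                   splits=None) -> CrossValReport:
    """k-fold cross-validation of the GCN-MME on a fixed fused graph.

    The graph and feature selection are built once over all patients
    before splitting (the transductive protocol); each fold trains from a
    fresh initialization and is scored on its held-out test mask.
    """
    if splits is None:
        union_labels = labels.subset(manifest.union_ids)
        splits = make_splits(union_labels, config.n_folds, config.val_frac,
                             config.seed)
    results = _run_folds(matrices, graph, manifest, labels, config, splits)
    accs = np.array([r["report"].accuracy for r in results])
    f1s = np.array([r["report"].weighted_f1 for r in results])
    vals = np.array([r["val_accuracy"] for r in results])
    return CrossValReport(
        folds=[r["report"] for r in results],
        accuracy_mean=float(accs.mean()), accuracy_sd=float(accs.std()),
        f1_mean=float(f1s.mean()), f1_sd=float(f1s.std()),
        val_accuracy_mean=float(np.nanmean(vals)),
    )


def ablate_modalities(matrices, labels: LabelSet, config: RunConfig,
                      mode: str = "leave_one_out") -> list:
    """Cross-validate modality subsets to attribute predictive power.

    ``matrices`` are the preprocessed, feature-selected per-modality
    matrices. ``leave_one_out`` drops one modality at a time;
    ``all_subsets`` enumerates every non-empty subset (refused above 6
    modalities). Each subset rebuilds its own manifest, fused network and
    graph, so patient coverage varies with the subset. Results are sorted
    by mean test accuracy, best first.
    """
    from .pipeline import build_network  # local import to avoid a cycle

    matrices = list(matrices)
    names = [m.modality_name for m in matrices]
    if mode == "leave_one_out":
        if len(matrices) < 2:
            raise ValueError("leave_one_out needs at least 2 modalities")
        subsets = [tuple(n for n in names if n != drop) for drop in names]
    elif mode == "all_subsets":
        if len(matrices) > 6:
            raise ValueError("all_subsets with more than 6 modalities explodes "
                             "combinatorially; use leave_one_out")
        subsets = [
            combo
            for r in range(1, len(names) + 1)
            for combo in itertools.combinations(names, r)
        ]
    else:
        raise ValueError(f"unknown ablation mode {mode!r}")

    by_name = {m.modality_name: m for m in matrices}
    results = []
    for subset in subsets:
        sub = [by_name[n] for n in subset]
        graph, fused, manifest = build_network(sub, config)
        report = cross_validate(sub, graph, manifest, labels, config)
        results.append(AblationResult(subset, report, manifest.n_patients))
    results.sort(key=lambda r: (-r.report.accuracy_mean, len(r.modalities),
                                r.modalities))
    return results


def hyperparameter_search(matrices, graph: PatientGraph, manifest: SampleManifest,
                          labels: LabelSet, grid: dict,
                          config: RunConfig):
    """Grid search over latent and shared dimensions on validation accuracy.

    ``grid`` maps any of ``latent_dim`` / ``shared_dim`` / ``gcn_hidden``
    to candidate lists. The configuration maximizing mean validation
    accuracy wins; ties go to the smaller total dimension.

    Returns
    -------
    (RunConfig, DataFrame)
        The winning configuration and the full score table.
    """
    keys = sorted(grid)
    if not keys or any(len(grid[k]) == 0 for k in keys):
        raise ValueError("hyperparameter grid is empty")
    unknown = [k for k in keys if k not in ("latent_dim", "shared_dim", "gcn_hidden")]
    if unknown:
        raise ValueError(f"unsupported grid keys: {unknown}")
    union_labels = labels.subset(manifest.union_ids)
    splits = make_splits(union_labels, config.n_folds, config.val_frac, config.seed)
    rows = []
    best = None
    for combo in itertools.product(*(grid[k] for k in keys)):
        cand = replace(config, **dict(zip(keys, combo)))
        results = _run_folds(matrices, graph, manifest, labels, cand, splits)
        score = float(np.mean([r["val_accuracy"] for r in results]))
        total_dim = sum(int(v) for v in combo)
        rows.append({**dict(zip(keys, combo)), "val_accuracy": score})
        key = (-score, total_dim)
        if best is None or key < best[0]:
            best = (key, cand)
    return best[1], pd.DataFrame(rows)
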