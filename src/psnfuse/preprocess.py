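"""Per-modality cleaning and supervised feature extraction.

Count modalities (mRNA/miRNA) go through: uninformative-feature removal,
median-of-ratios normalization, connectivity-based sample outlier removal,
and one-vs-rest differential expression with Benjamini-Hochberg control.
Bounded or continuous modalities (DNAm beta-values, CNV, RPPA) go through:
missingness filtering with mean imputation, an optional log transform, and
multinomial elastic-net feature selection.

The differential-expression engine is a self-contained one-vs-rest Welch t
test on log2 normalized counts with pooled BH adjustment; the selection
contract is "adjusted p below alpha", not bit-identity with any particular
negative-binomial GLM implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .containers import LabelSet, OmicsMatrix


@dataclass
class FeatureSelectionResult:
    """Outcome of a supervised feature-selection pass on one modality."""

    modality_name: str
    selected_feature_ids: list
    table: pd.DataFrame
    method: str

    def write(self, path) -> None:
        sep = "," if str(path).lower().endswith(".csv") else "\t"
        self.table.to_csv(path, sep=sep, index=False)


def filter_uninformative_features(m: OmicsMatrix) -> OmicsMatrix:
    """Drop features with all-zero observed values or zero variance.

    Feature order of the survivors is preserved. Raises if nothing would
    survive, which almost always signals a malformed input matrix.
    """
    with np.errstate(invalid="ignore"):
        all_zero = np.nansum(np.abs(m.values), axis=0) == 0
        var = np.nanvar(m.values, axis=0)
    zero_var = var == 0
    keep = ~(all_zero | zero_var)
    if not keep.any():
        raise ValueError(
            f"all features of {m.modality_name!r} are zero or constant; "
            "inspect the input matrix"
        )
    kept = [f for f, k in zip(m.feature_ids, keep) if k]
    return m.replace_values(m.values[:, keep], feature_ids=kept)


def normalize_counts(m: OmicsMatrix):
    """Median-of-ratios (DESeq2-style) library-size normalization.

    Size factors are computed from features with strictly positive counts
    in every sample: each sample's factor is the median across those
    features of the ratio count / geometric-mean count. Every sample row
    is divided by its factor.

    Returns
    -------
    (OmicsMatrix, ndarray)
        The normalized matrix and the per-sample size factors.
    """
    if m.data_kind != "counts":
        raise ValueError("normalize_counts expects a counts matrix")
    if m.missing_mask.any():
        raise ValueError("counts matrix must be complete before normalization")
    x = m.values
    positive = (x > 0).all(axis=0)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; consider adding "
            "a pseudo-count before normalization"
        )
    logs = np.log(x[:, positive])
    log_geomean = logs.mean(axis=0)
    size_factors = np.exp(np.median(logs - log_geomean, axis=1))
    out = m.replace_values(x / size_factors[:, None])
    return out, size_factors


def remove_outlier_samples(m: OmicsMatrix, sd: float = 2.0):
    """Remove samples whose correlation connectivity is an outlier.

    Connectivity of a sample is the sum of its Pearson correlations to all
    other samples. Samples more than ``sd`` standard deviations from the
    mean connectivity (two-sided) are removed.

    Returns
    -------
    (OmicsMatrix, list)
        Filtered matrix and the removed sample IDs.
    """
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples for outlier detection")
    if m.missing_mask.any():
        raise ValueError("matrix must be complete for connectivity computation")
    sd = float(sd)
    row_sd = m.values.std(axis=1)
    if (row_sd == 0).any():
        bad = m.sample_ids[int(np.argmax(row_sd == 0))]
        raise ValueError(f"sample {bad!r} has zero variance across features")
    corr = np.corrcoef(m.values)
    connectivity = corr.sum(axis=1) - 1.0  # exclude self-correlation
    c_sd = connectivity.std()
    if c_sd == 0 or not np.isfinite(sd):
        return m, []
    z = (connectivity - connectivity.mean()) / c_sd
    keep = np.abs(z) <= sd
    if not keep.any():
        raise ValueError("outlier rule would remove every sample")
    removed = [s for s, k in zip(m.sample_ids, keep) if not k]
    if not removed:
        return m, []
    kept_ids = [s for s, k in zip(m.sample_ids, keep) if k]
    return m.select_samples(kept_ids), removed


def de_one_vs_rest(m: OmicsMatrix, labels: LabelSet, alpha: float = 0.05) -> FeatureSelectionResult:
    """One-vs-rest differential expression on log2 normalized counts.

    For each class c and feature f, a Welch t test compares class-c samples
    against all others on log2(x + 1). All (feature, class) p-values are
    pooled and Benjamini-Hochberg adjusted; a feature is selected if any of
    its class contrasts has adjusted p < alpha.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    if m.missing_mask.any():
        raise ValueError("counts matrix must be complete for DE")
    y = np.array([labels.label_of(s) for s in m.sample_ids], dtype=object)
    logx = np.log2(m.values + 1.0)
    rows = []
    for c in labels.class_names:
        in_c = y == c
        if in_c.sum() < 2 or (~in_c).sum() < 2:
            raise ValueError(f"class {c!r} needs >= 2 samples on each side of the contrast")
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(logx[in_c], logx[~in_c], axis=0, equal_var=False)
        effect = logx[in_c].mean(axis=0) - logx[~in_c].mean(axis=0)
        p = np.where(np.isnan(p), 1.0, p)
        t = np.where(np.isnan(t), 0.0, t)
        rows.append(pd.DataFrame({
            "feature": m.feature_ids, "class": c,
            "log2fc": effect, "stat": t, "p": p,
        }))
    table = pd.concat(rows, ignore_index=True)
    if alpha == 0:
        table["adj_p"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
        table["selected"] = False
    else:
        rejected, adj_p, _, _ = multipletests(table["p"].to_numpy(), alpha=alpha,
                                              method="fdr_bh")
        table["adj_p"] = adj_p
        table["selected"] = adj_p < alpha
    sel_set = set(table.loc[table["selected"], "feature"])
    selected = [f for f in m.feature_ids if f in sel_set]
    return FeatureSelectionResult(m.modality_name, selected, table, "de_one_vs_rest")


def filter_missingness(m: OmicsMatrix, threshold: float = 0.5) -> OmicsMatrix:
    """Drop features over the missingness threshold; mean-impute the rest.

    A feature is removed when its fraction of missing entries exceeds
    ``threshold``; remaining missing entries are replaced by the feature's
    observed mean, so the output carries no missing values.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    frac = m.missing_mask.mean(axis=0)
    keep = frac <= threshold
    fully_missing_kept = keep & (frac == 1.0)
    if fully_missing_kept.any():
        f = m.feature_ids[int(np.argmax(fully_missing_kept))]
        raise ValueError(f"feature {f!r} is entirely missing; cannot impute its mean")
    if not keep.any():
        raise ValueError("missingness filter would remove every feature")
    kept = [f for f, k in zip(m.feature_ids, keep) if k]
    vals = m.values[:, keep].copy()
    col_means = np.nanmean(vals, axis=0)
    nan_r, nan_c = np.where(np.isnan(vals))
    vals[nan_r, nan_c] = col_means[nan_c]
    return m.replace_values(vals, feature_ids=kept)


def log_transform(m: OmicsMatrix):
    """Elementwise log(x + offset) with offset = 1 - min(0, global minimum).

    The offset guarantees the log argument is >= 1 wherever values are
    observed, so the transform is defined for matrices containing negative
    entries (e.g. copy-number log ratios).

    Returns
    -------
    (OmicsMatrix, float)
        Transformed matrix and the offset used.
    """
    gmin = np.nanmin(m.values) if m.values.size else 0.0
    offset = 1.0 - min(0.0, float(gmin))
    with np.errstate(invalid="ignore"):
        vals = np.log(m.values + offset)
    return m.replace_values(vals), offset


def elastic_net_select(m: OmicsMatrix, labels: LabelSet, mixing: float = 0.5,
                       C: float | None = None, n_candidates: int = 8,
                       cv: int = 5, seed: int = 0,
                       max_iter: int = 3000) -> FeatureSelectionResult:
    """Multinomial elastic-net feature selection.

    Features are standardized internally; the penalty strength is chosen
    by internal stratified cross-validation over a log-spaced path with a
    one-standard-error rule (strongest penalty whose mean CV accuracy is
    within one SE of the best). A feature is selected when any class has a
    nonzero coefficient at the chosen penalty. Pass ``C`` to skip the CV
    and fit at a fixed inverse penalty strength.
    """
    if not 0 <= mixing <= 1:
        raise ValueError("mixing must be in [0, 1]")
    if m.missing_mask.any():
        raise ValueError("matrix must be complete (run filter_missingness first)")
    y = np.array([labels.label_of(s) for s in m.sample_ids], dtype=object)
    if len(set(y)) < 2:
        raise ValueError("elastic-net selection needs >= 2 classes present")
    x = m.values
    mu, sdev = x.mean(axis=0), x.std(axis=0)
    sdev = np.where(sdev == 0, 1.0, sdev)
    xs = (x - mu) / sdev

    if C is None:
        cs = np.logspace(-3, 1, n_candidates)
        skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        cv_model = LogisticRegressionCV(
            Cs=cs, cv=skf, solver="saga", l1_ratios=[mixing], scoring="accuracy",
            max_iter=max_iter, tol=1e-4, random_state=seed,
            use_legacy_attributes=True)
        cv_model.fit(xs, y)
        # scores_: per class key, folds x Cs (x l1_ratios); identical across keys
        scores = next(iter(cv_model.scores_.values()))
        scores = scores.reshape(scores.shape[0], len(cs))
        mean_acc = scores.mean(axis=0)
        best = int(np.argmax(mean_acc))
        se_best = scores[:, best].std(ddof=1) / np.sqrt(scores.shape[0])
        # 1-SE rule: smallest C (strongest penalty) within one SE of the best
        ok = np.where(mean_acc >= mean_acc[best] - se_best)[0]
        C = float(cs[ok[0]])
    model = LogisticRegression(C=C, solver="saga", l1_ratio=mixing,
                               max_iter=max_iter, tol=1e-4, random_state=seed)
    model.fit(xs, y)
    coef = model.coef_  # n_classes (or 1 for binary) x n_features
    if coef.shape[0] == 1:
        coef = np.vstack([-coef, coef])
    magnitude = np.abs(coef).max(axis=0)
    nonzero = magnitude > 0
    table = pd.DataFrame({
        "feature": m.feature_ids,
        "coef_magnitude": magnitude,
        "selected": nonzero,
    })
    selected = [f for f, k in zip(m.feature_ids, nonzero) if k]
    return FeatureSelectionResult(m.modality_name, selected, table, "elastic_net")
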