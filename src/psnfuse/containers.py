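"""Core in-memory containers shared by every stage of the pipeline.

All downstream modules consume these types rather than raw files: a
per-modality samples x features matrix (:class:`OmicsMatrix`), the class
labels (:class:`LabelSet`), the union-of-patients bookkeeping
(:class:`SampleManifest`), and the weighted patient graph
(:class:`PatientGraph`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DATA_KINDS = ("counts", "beta", "continuous")


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} ID: {i!r}")
        seen.add(i)


@dataclass
class OmicsMatrix:
    """One modality's samples x features table.

    Rows are patients (samples), columns are features. Missing entries are
    stored as NaN in ``values`` and flagged in ``missing_mask``.

    Parameters
    ----------
    modality_name : str
        Name of the modality (e.g. ``"mRNA"``, ``"DNAm"``).
    sample_ids, feature_ids : list of str
        Ordered, unique row / column identifiers.
    values : ndarray of shape (n_samples, n_features)
        Measurements; NaN exactly where ``missing_mask`` is True.
    data_kind : {"counts", "beta", "continuous"}
        Declared measurement type. Counts must be non-negative and
        beta-values (methylation proportions) must lie in [0, 1].
    """

    modality_name: str
    sample_ids: list
    feature_ids: list
    values: np.ndarray
    data_kind: str
    missing_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if self.data_kind not in DATA_KINDS:
            raise ValueError(f"unknown data_kind {self.data_kind!r}; expected one of {DATA_KINDS}")
        nan_mask = np.isnan(self.values)
        if self.missing_mask is None:
            self.missing_mask = nan_mask
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape does not match values")
            if not np.array_equal(self.missing_mask, nan_mask):
                raise ValueError("missing_mask must be True exactly where values are NaN")
        self._validate_kind()

    def _validate_kind(self) -> None:
        obs = ~self.missing_mask
        if self.data_kind == "counts":
            bad = obs & (self.values < 0)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"negative count {self.values[i, j]} at sample "
                    f"{self.sample_ids[i]!r}, feature {self.feature_ids[j]!r}"
                )
        elif self.data_kind == "beta":
            bad = obs & ((self.values < 0) | (self.values > 1))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"beta value {self.values[i, j]} outside [0, 1] at sample "
                    f"{self.sample_ids[i]!r}, feature {self.feature_ids[j]!r}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def select_features(self, feature_ids) -> "OmicsMatrix":
        """Return a copy restricted to ``feature_ids`` (order as given)."""
        idx = {f: j for j, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in idx]
        if missing:
            raise KeyError(f"unknown feature IDs: {missing[:5]}")
        cols = [idx[f] for f in feature_ids]
        return OmicsMatrix(
            self.modality_name, self.sample_ids, list(feature_ids),
            self.values[:, cols], self.data_kind,
        )

    def select_samples(self, sample_ids) -> "OmicsMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"unknown sample IDs: {missing[:5]}")
        rows = [idx[s] for s in sample_ids]
        return OmicsMatrix(
            self.modality_name, list(sample_ids), self.feature_ids,
            self.values[rows], self.data_kind,
        )

    def replace_values(self, values, feature_ids=None, sample_ids=None) -> "OmicsMatrix":
        return OmicsMatrix(
            self.modality_name,
            self.sample_ids if sample_ids is None else list(sample_ids),
            self.feature_ids if feature_ids is None else list(feature_ids),
            values,
            self.data_kind,
        )


@dataclass
class LabelSet:
    """Class label per sample; ``class_names`` in first-appearance order."""

    sample_ids: list
    classes: list
    class_names: list = field(default=None)

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.classes = list(self.classes)
        _check_unique(self.sample_ids, "sample")
        if len(self.classes) != len(self.sample_ids):
            raise ValueError("classes and sample_ids length mismatch")
        if self.class_names is None:
            seen = []
            for c in self.classes:
                if c not in seen:
                    seen.append(c)
            self.class_names = seen
        else:
            self.class_names = list(self.class_names)
        _check_unique(self.class_names, "class")
        unknown = set(self.classes) - set(self.class_names)
        if unknown:
            raise ValueError(f"labels not in class_names: {sorted(unknown)}")
        if len(set(self.classes)) < 2:
            raise ValueError("need at least 2 distinct classes")
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def label_of(self, sample_id):
        if sample_id not in self._index:
            raise KeyError(f"unknown sample ID {sample_id!r}")
        return self.classes[self._index[sample_id]]

    def codes_for(self, sample_ids) -> np.ndarray:
        """Integer class codes (index into class_names) for the given samples."""
        code = {c: k for k, c in enumerate(self.class_names)}
        return np.array([code[self.label_of(s)] for s in sample_ids], dtype=int)

    def subset(self, sample_ids) -> "LabelSet":
        return LabelSet(list(sample_ids), [self.label_of(s) for s in sample_ids],
                        self.class_names)


@dataclass
class SampleManifest:
    """Union-of-patients bookkeeping: which patient is observed in which modality.

    ``observed`` is a boolean patient x modality table indexed by the
    lexicographically sorted union of all modality sample IDs.
    """

    union_ids: list
    observed: pd.DataFrame

    def __post_init__(self):
        self.union_ids = list(self.union_ids)
        _check_unique(self.union_ids, "patient")
        if list(self.observed.index) != self.union_ids:
            raise ValueError("observed table index must equal union_ids")
        if not self.observed.to_numpy().any(axis=1).all():
            bad = [p for p, row in self.observed.iterrows() if not row.any()]
            raise ValueError(f"patients observed in no modality: {bad[:5]}")

    @property
    def modalities(self) -> list:
        return list(self.observed.columns)

    @property
    def n_patients(self) -> int:
        return len(self.union_ids)

    @property
    def intersection_size(self) -> int:
        return int(self.observed.to_numpy().all(axis=1).sum())

    def observed_ids(self, modality: str) -> list:
        col = self.observed[modality].to_numpy()
        return [p for p, o in zip(self.union_ids, col) if o]

    def union_increase_pct(self) -> float:
        """Percent gain in patient coverage of the union over the intersection.

        100 * (n_union - n_intersection) / n_intersection — the payoff of a
        union-of-patients integration strategy over requiring every patient
        to be measured in every modality.
        """
        n_int = self.intersection_size
        if n_int == 0:
            raise ValueError("empty intersection; percent increase undefined")
        return 100.0 * (self.n_patients - n_int) / n_int


def build_manifest(matrices) -> SampleManifest:
    """Build the union-of-patients manifest from a list of OmicsMatrix.

    Union IDs are sorted lexicographically; observation flags are True iff
    the patient appears in that modality. Idempotent and invariant to the
    order of the modality list.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("need at least one modality matrix")
    names = [m.modality_name for m in matrices]
    _check_unique(names, "modality")
    union = sorted(set().union(*[set(m.sample_ids) for m in matrices]))
    flags = {
        m.modality_name: [s in set(m.sample_ids) for s in union] for m in matrices
    }
    observed = pd.DataFrame(flags, index=union, columns=names).astype(bool)
    return SampleManifest(union, observed)


@dataclass
class PatientGraph:
    """Weighted undirected network over patient IDs.

    ``weights`` is a dense symmetric matrix with zero diagonal; an edge
    exists where the weight is positive. ``adjacency`` is the binary view
    consumed by the GCN.
    """

    patient_ids: list
    weights: np.ndarray

    def __post_init__(self):
        self.patient_ids = list(self.patient_ids)
        _check_unique(self.patient_ids, "patient")
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.patient_ids)
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square over patient_ids")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.diag(self.weights).any():
            raise ValueError("self-loops are not allowed")
        if (self.weights < 0).any():
            raise ValueError("edge weights must be non-negative")

    @property
    def n_nodes(self) -> int:
        return len(self.patient_ids)

    @property
    def adjacency(self) -> np.ndarray:
        return (self.weights > 0).astype(float)

    def edges(self):
        """Sorted list of (u, v, weight) with u < v."""
        out = []
        n = self.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                w = self.weights[i, j]
                if w > 0:
                    out.append((self.patient_ids[i], self.patient_ids[j], float(w)))
        return out

    def degree(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=1)
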