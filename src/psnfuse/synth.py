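"""Synthetic multi-omic data with planted class structure.

The generator emulates the statistical shape the pipeline assumes from
real cohorts: a count modality (RNA-seq-like negative-binomial counts with
log-uniform baseline means and fixed overdispersion), a bounded modality
(methylation-like beta-values produced by a logistic transform of latent
Gaussians), and a continuous modality (protein-array-like Gaussians).
Class signal is planted in a subset of features per modality, each
informative feature elevated in exactly one class: a log2 fold change for
counts, a logit shift for beta-values, and a mean shift in SD units for
continuous values. Per-modality patient dropout and completely-at-random
entry-level missingness mirror the union-of-patients setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import LabelSet, OmicsMatrix

NB_DISPERSION = 0.2          # var = mu + disp * mu^2
COUNT_MEAN_RANGE = (20.0, 2000.0)


@dataclass
class ModalitySpec:
    """Shape and planted signal of one synthetic modality."""

    name: str
    data_kind: str
    n_features: int
    n_informative: int
    effect_size: float
    patient_missing_frac: float = 0.0
    entry_missing_frac: float = 0.0

    def __post_init__(self):
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must be <= n_features")
        for f in ("patient_missing_frac", "entry_missing_frac"):
            v = getattr(self, f)
            if not 0 <= v < 1:
                raise ValueError(f"{f} must be in [0, 1)")


@dataclass
class GeneratorSpec:
    """Full study design for one synthetic multi-omic dataset."""

    n_patients: int = 300
    n_classes: int = 3
    class_proportions: list = field(default=None)
    modalities: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2 or self.n_classes < 2:
            raise ValueError("need >= 2 patients and >= 2 classes")
        if self.class_proportions is None:
            self.class_proportions = [1.0 / self.n_classes] * self.n_classes
        if len(self.class_proportions) != self.n_classes:
            raise ValueError("class_proportions length must equal n_classes")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        self.modalities = [
            m if isinstance(m, ModalitySpec) else ModalitySpec(**m)
            for m in self.modalities
        ]
        if not self.modalities:
            raise ValueError("need at least one modality spec")

    @classmethod
    def default(cls, seed: int = 0) -> "GeneratorSpec":
        """The reference study design: 300 patients, 3 balanced classes,
        three modalities (counts / beta / continuous) each missing 20% of
        patients, with moderate planted effects."""
        return cls(
            n_patients=300,
            n_classes=3,
            modalities=[
                ModalitySpec("mrna", "counts", n_features=300, n_informative=30,
                             effect_size=2.0, patient_missing_frac=0.2),
                ModalitySpec("dnam", "beta", n_features=250, n_informative=30,
                             effect_size=2.0, patient_missing_frac=0.2,
                             entry_missing_frac=0.02),
                ModalitySpec("protein", "continuous", n_features=150,
                             n_informative=25, effect_size=1.5,
                             patient_missing_frac=0.2, entry_missing_frac=0.02),
            ],
            seed=seed,
        )


def _largest_remainder(total: int, proportions) -> np.ndarray:
    raw = np.asarray(proportions) * total
    counts = np.floor(raw).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def _nb_draw(rng, mean):
    r = 1.0 / NB_DISPERSION
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def generate_multiomics(spec: GeneratorSpec):
    """Generate per-modality matrices, labels and the planted-signal truth.

    Returns
    -------
    (list of OmicsMatrix, LabelSet, dict)
        The truth record maps each modality to its informative feature ->
        elevated class, and records the class assignment.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    patients = [f"P{i:04d}" for i in range(n)]
    class_names = [f"C{k}" for k in range(spec.n_classes)]
    counts = _largest_remainder(n, spec.class_proportions)
    codes = np.repeat(np.arange(spec.n_classes), counts)
    codes = codes[rng.permutation(n)]
    labels = LabelSet(patients, [class_names[c] for c in codes], class_names)

    # per-modality patient dropout, exact floor(frac * n) absences each
    missing_sets = []
    for m in spec.modalities:
        k = int(np.floor(m.patient_missing_frac * n))
        missing_sets.append(set(rng.choice(n, size=k, replace=False)) if k else set())
    # repair: every patient must stay observed in at least one modality
    if len(missing_sets) > 1:
        for i in range(n):
            if all(i in s for s in missing_sets):
                s = missing_sets[-1]
                s.remove(i)
                swap = next(j for j in range(n)
                            if j not in s and sum(j in t for t in missing_sets) == 0)
                s.add(swap)

    truth = {"classes": dict(zip(patients, labels.classes)), "informative": {}}
    matrices = []
    for m, missing in zip(spec.modalities, missing_sets):
        keep = np.array([i for i in range(n) if i not in missing])
        y = codes[keep]
        nf, ni = m.n_features, m.n_informative
        feat_ids = [f"{m.name}_f{j:04d}" for j in range(nf)]
        target_class = {j: j % spec.n_classes for j in range(ni)}
        if m.data_kind == "counts":
            lo, hi = np.log10(COUNT_MEAN_RANGE[0]), np.log10(COUNT_MEAN_RANGE[1])
            base = 10 ** rng.uniform(lo, hi, size=nf)
            mu = np.tile(base, (len(keep), 1))
            for j, c in target_class.items():
                mu[y == c, j] *= 2.0 ** m.effect_size
            values = _nb_draw(rng, mu)
        elif m.data_kind == "beta":
            centre = rng.normal(0.0, 1.5, size=nf)
            latent = rng.normal(0.0, 1.0, size=(len(keep), nf)) + centre
            for j, c in target_class.items():
                latent[y == c, j] += m.effect_size
            values = 1.0 / (1.0 + np.exp(-latent))
        elif m.data_kind == "continuous":
            values = rng.normal(0.0, 1.0, size=(len(keep), nf))
            for j, c in target_class.items():
                values[y == c, j] += m.effect_size
        else:  # pragma: no cover - guarded by ModalitySpec/OmicsMatrix
            raise ValueError(f"unknown data_kind {m.data_kind!r}")
        if m.entry_missing_frac > 0:
            hole = rng.random(values.shape) < m.entry_missing_frac
            values = values.astype(float)
            values[hole] = np.nan
        matrices.append(OmicsMatrix(
            m.name, [patients[i] for i in keep], feat_ids, values, m.data_kind))
        truth["informative"][m.name] = {
            feat_ids[j]: class_names[c] for j, c in target_class.items()
        }
    return matrices, labels, truth


def generate_null_counts(n: int, p: int, seed: int = 0) -> OmicsMatrix:
    """Label-independent negative-binomial counts for type-I-error testing."""
    if n < 2 or p < 2:
        raise ValueError("need n >= 2 samples and p >= 2 features")
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(COUNT_MEAN_RANGE[0]), np.log10(COUNT_MEAN_RANGE[1])
    base = 10 ** rng.uniform(lo, hi, size=p)
    values = _nb_draw(rng, np.tile(base, (n, 1)))
    ids = [f"N{i:04d}" for i in range(n)]
    feats = [f"null_f{j:04d}" for j in range(p)]
    return OmicsMatrix("null_counts", ids, feats, values, "counts")
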