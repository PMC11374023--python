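# Methods

## Problem setting

Given several omic measurements (modalities) on overlapping but not
identical sets of patients — RNA-seq counts, methylation beta-values,
protein or copy-number values — the task is to classify every patient
into a disease subtype or grade while (a) using the *union* of patients
rather than the intersection, and (b) letting modalities reinforce each
other instead of being concatenated. The pipeline has three stages:
per-modality feature selection, similarity-network fusion into one
patient graph, and a jointly trained multi-modal encoder + graph
convolutional network (GCN-MME).

## Preprocessing and feature selection

Count modalities (mRNA, miRNA): features with all-zero or zero-variance
observed values are dropped; library sizes are normalized by
median-of-ratios size factors (each sample's factor is the median, over
features positive in every sample, of its count divided by the feature's
geometric mean); samples whose *connectivity* — the sum of their Pearson
correlations to all other samples — lies more than `outlier_sd` (default
2) standard deviations from the mean connectivity are removed, two-sided.
Differential expression is one-vs-rest per class: a Welch t test on
log2(normalized + 1) per feature, all (feature, class) p-values pooled
into a single Benjamini–Hochberg adjustment, and a feature is selected if
any class contrast has adjusted p < `de_alpha` (default 0.05). This is a
deliberately self-contained selector: the contract consumed downstream is
the adjusted-p threshold, and no bit-compatibility with a negative-
binomial GLM engine is claimed. Pooling BH across classes (rather than
per class) keeps one coherent false-discovery rate over the union of
selections.

Bounded/continuous modalities (DNAm, CNV, RPPA): features with a missing
fraction above `missingness_threshold` (default 0.5) are dropped and the
rest mean-imputed from observed values, so downstream stages see complete
matrices; continuous modalities may be log-transformed with offset
`1 − min(0, global minimum)` so the argument never falls below 1; feature
selection is a multinomial elastic net (mixing default 0.5) with the
penalty chosen by internal stratified 5-fold cross-validation and a
one-standard-error rule (the strongest penalty whose mean CV accuracy is
within one SE of the best). A feature is selected if any class carries a
nonzero coefficient.

If a selector returns fewer than two features (possible on null-like
data), the two top-ranked features are kept so that the similarity stage
remains defined; the run is then effectively signal-free and behaves like
a null model.

## Patient similarity and fusion

Similarity between patients is the Pearson correlation of their selected
feature vectors for counts and beta-values, and Euclidean distance for
continuous modalities where correlation across heterogeneous scales is
less meaningful. Correlation silently falls back to Euclidean distance
when it is unsuitable: fewer than three selected features, or a patient
constant across them (both arise on signal-free data, where selection
degenerates to its minimal fallback). Each modality's similarity matrix becomes an affinity
via the scaled exponential kernel
`W[i,j] = exp(−d²(i,j) / (mu · ε_ij))` with
`ε_ij = (mean_K(i) + mean_K(j) + d(i,j)) / 3`, where `mean_K` is a
point's mean distance to its K nearest neighbours and `d = 1 − r` for
correlation. Defaults `K = 20` (capped at n−1), `mu = 0.5`, `T = 20`
iterations follow the conventions of the fusion literature; the source
publications for this pipeline do not state them.

Fusion is standard SNF cross-diffusion: per modality a row-normalized
full kernel `P_v` (off-diagonal mass 1/2, diagonal 1/2) and a K-NN
restricted row-stochastic kernel `S_v`; for `T` iterations
`P_v ← S_v · mean_{w≠v}(P_w) · S_vᵀ`, renormalized and symmetrized; the
fused network is the elementwise mean of the final `P_v`. With one
modality, fusion is defined as normalize-and-symmetrize with no
diffusion (the update is undefined for a single view).

**Partial patient overlap.** Each modality diffuses on its own observed
block. Where a pair of patients is covered by no *other* modality, the
cross-modal mean falls back to the modality's own entry; fused entries
average only over modalities observing both patients, and pairs covered
by no modality are zero. Under full overlap this reduces exactly to
textbook SNF (verified against a straight-line implementation of the
update equations in the test suite).

The final graph is the K-nearest-neighbour sparsification of the fused
affinities with `k_neighbours = 15`, symmetrized by union (an edge exists
if either endpoint selects the other; mutual-KNN is available behind
`mutual_knn`). Ranking ties are broken by patient ID for determinism.
The GCN consumes the binary adjacency; fused weights are retained on
edges for reporting only, since the propagation rule below does not
define edge weights.

## GCN-MME

Each modality is encoded by a two-layer network: a linear layer of width
`encoder_hidden` (default 500) with ReLU, then a linear layer to the
modality's latent width (`latent_dim`, capped at the feature count).
Patients missing from a modality receive the per-dimension **median** of
the observed patients' latent rows (midpoint convention for even counts),
recomputed at every forward pass; the median is treated as a constant in
backpropagation, so gradients reach encoders only through observed
patients. Latents are linearly projected (learned per modality) to a
shared dimension `shared_dim` and mean-pooled into the node feature
matrix X.

Two graph convolutions follow the propagation rule
`H(l+1) = σ(L H(l) W(l))` with `L = D̃^{-1/2} Ã D̃^{-1/2}`, `Ã = A + I`:
a first layer of width `gcn_hidden` with ReLU and batch normalization
(after the activation; automatically disabled below 8 nodes where batch
statistics degenerate), then a linear layer to the class logits.

Training is fully transductive: every node participates in message
passing, but the cross-entropy loss averages over **training-mask nodes
only**; validation labels steer early stopping and test labels are never
read by the optimizer (checked bit-exactly in the test suite). The whole
stack — encoders, projections, GCN, batch norm, Adam — is implemented
directly in numpy with hand-derived gradients, which keeps runs
bit-reproducible from a single integer seed (weight initialization is
the only random element) and the dependency surface minimal. Optimizer
defaults: Adam, learning rate 1e-3, weight decay 5e-4 on weight matrices,
at most 500 epochs with patience 50 on validation loss; the best
validation-epoch weights are restored.

## Evaluation protocol

Stratified k-fold cross-validation (default 5 folds) partitions the
labelled patients into test folds; within each fold, 15% of the non-test
patients (largest-remainder rounding per class) form the validation set,
giving the 68% / 12% / 20% train/validation/test geometry at n = 100.
Metrics are accuracy and class-size-weighted F1, aggregated as mean ±
population SD over folds, with per-class precision/recall/F1 and
one-vs-rest AUC when probabilities are available. Splits are stratified
because subtype imbalance makes unstratified small folds fragile.

Feature selection and the fused graph are built **once over all
patients** before splitting: this mirrors the transductive design (one
shared network across folds) and is cheaper, but lets test-patient
features (never labels) influence selection and graph structure. The
leakage-strict alternative — supervised selection refit inside each fold
on train + validation patients only — is available via
`per_fold_selection`.

Ablation re-runs the full network construction and CV on modality
subsets (leave-one-out, or all subsets up to 6 modalities), reporting
each subset's patient coverage, since dropping a modality also drops the
patients only it observes. Hyperparameter search grids over latent,
shared and hidden dimensions on mean validation accuracy, breaking ties
toward the smaller model.

## Synthetic data

The generator emulates the statistical shape of multi-omic cohorts, not
their biology: negative-binomial counts (dispersion 0.2, baseline means
log-uniform on [20, 2000] — RNA-seq-like overdispersion at desk scale),
beta-values as logistic transforms of latent Gaussians, and Gaussian
continuous features. Each informative feature is elevated in exactly one
class: log2 fold change for counts, logit shift for beta, mean shift in
SD units for continuous. Per-modality patient dropout removes exactly
⌊frac·n⌋ patients (repaired so everyone stays observed somewhere), and
entry-level missingness is completely at random — matching the
mean-imputation assumption. The reference design is 300 patients, 3
balanced classes, three modalities (counts / beta / continuous) each
missing 20% of patients, with effects lfc = 2, logit shift = 2, and 1.5
SD.

What passing on this generator does **not** show: robustness to batch
effects, correlated feature blocks, segment-structured copy number,
probe-type effects in methylation, informative (non-random) missingness,
or class-dependent dropout. Real-cohort performance claims require real
cohorts.

One model-level property deserves a note: integrating modalities beats
the best single modality only when the modalities carry *complementary*
signal. With the same weak signal duplicated in every modality, fusing
adds noise as fast as information, and the fused model can trail a good
singleton. The test suite therefore checks the integration advantage on
a complementary design (each modality separates a different class), where
integration is the only route to resolving all classes.

## Numerical choices and edge cases

- Missing values are NaN internally; readers accept empty fields or any
  capitalisation of ``NA`` and writers emit ``NA``.
- Union patient ordering is lexicographic everywhere, for cross-platform
  determinism.
- Pearson edge weights in KNN graphs are floored at 1e-20 so a selected
  negative-correlation edge is kept rather than silently dropped.
- SNF kernel ε is floored at 1e-20; rows with zero off-diagonal mass
  normalize to an identity-like row.
- Batch-norm ε is 1e-5, momentum 0.1 for running statistics; evaluation
  always uses running statistics, which preserves permutation
  equivariance of predictions.
- Model seeds per CV fold are `seed + fold_id`, so folds are independent
  but the whole CV is reproducible from one seed.
- Problem sizes in the test suite (tens to hundreds of patients, tens to
  thousands of features) are chosen so the full suite and the
  reproduction script each run in minutes on one CPU core.

## Known limitations

- The DE selector is a t-test contract, not a count-model GLM; very low
  counts with few replicates will behave differently from a negative-
  binomial analysis.
- Transductive training means new patients require graph reconstruction
  and retraining; no inductive variant is provided.
- The "connectivity" outlier rule assumes correlation-based connectivity
  is meaningful for the modality; it is only applied to counts.
- Dense matrices throughout: fine for cohort-scale data (hundreds to a
  few thousand patients), not for biobank scale.
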