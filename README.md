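# psnfuse

Multi-omic data integration for classifying heterogeneous diseases:
per-modality patient-similarity networks are fused with Similarity
Network Fusion (SNF) over the **union of patients**, a jointly trained
multi-modal encoder (MME) compresses every modality into a shared latent
node-feature matrix, and a transductive graph convolutional network
(GCN) classifies every patient — including patients missing entire
modalities.

Intended users: computational biologists with several sample × feature
omic matrices (RNA-seq counts, methylation beta-values, protein arrays,
copy number) and a per-patient label (subtype, grade), who want one
classifier over all patients rather than the intersection measured in
every modality.

## Method in brief

1. **Feature selection.** Counts: median-of-ratios normalization,
   connectivity-outlier removal, one-vs-rest differential expression
   with pooled Benjamini–Hochberg, keep features with adjusted p < 0.05.
   Other modalities: missingness filter (> 50% dropped, rest
   mean-imputed), optional log transform, multinomial elastic-net
   selection.
2. **Network.** Per modality, patient similarity via Pearson correlation
   r = Σ(xᵢ−x̄)(yᵢ−ȳ) / √(Σ(xᵢ−x̄)² Σ(yᵢ−ȳ)²) where suitable, otherwise
   Euclidean distance; scaled exponential kernel affinities; SNF
   cross-diffusion Pᵥ ← Sᵥ · mean(P_w, w≠v) · Sᵥᵀ (T iterations) fuses
   the modalities; KNN sparsification (k = 15) gives the patient graph.
3. **GCN-MME.** Two-layer encoders per modality (hidden width D = 500),
   median imputation of latent rows for missing patients, learned
   projections mean-pooled into node features X; two graph convolutions
   H⁽ˡ⁺¹⁾ = σ(L H⁽ˡ⁾ W⁽ˡ⁾) with L = D̃^(−1/2) Ã D̃^(−1/2), Ã = A + I.
   Backpropagation runs jointly through GCN and encoders; the loss is
   masked to training nodes only (transductive semi-supervised
   training).
4. **Evaluation.** Stratified 5-fold CV with a 68/12/20
   train/validation/test geometry; accuracy and class-size-weighted F1
   as mean ± SD over folds; modality ablation and dimension search.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

`examples/04_train_and_classify.py` runs the full pipeline on the
reference synthetic design — 300 patients, 3 balanced classes, three
modalities (counts / beta / continuous) each missing 20% of patients:

```text
selected features per modality: {'mrna': 33, 'dnam': 23, 'protein': 25}
fused graph: 300 patients
accuracy    1.000 +/- 0.000
weighted F1 1.000 +/- 0.000
  fold 0, class C0: F1 1.000, AUC 1.000
  fold 0, class C1: F1 1.000, AUC 1.000
  fold 0, class C2: F1 1.000, AUC 1.000
```

Selection keeps ~30 features per modality (the planted signal), the
fused graph covers all 300 patients despite every modality missing 60,
and 5-fold cross-validated accuracy / weighted F1 are reported as mean ±
population SD over test folds. On this clean synthetic design the
classes are fully separable; `examples/03_fused_network.py` shows the
intermediate fused network (edge homophily 0.79 vs 0.33 at random) and
`examples/05_ablation_and_search.py` shows ablation correctly ranking a
signal-free modality last. Other examples cover simulation, feature
selection, and coverage bookkeeping.

The same pipeline is available as a CLI:

```bash
psnfuse simulate --outdir data/
psnfuse cv --config cfg.yaml --modality mrna=data/mrna.csv \
    --modality dnam=data/dnam.csv --modality protein=data/protein.csv \
    --labels data/labels.csv --outdir results/
```

## Layout

- `src/psnfuse/` — library: containers, io, preprocess, psn (similarity
  + SNF), gcn (GCN-MME), evaluate, pipeline, synth, cli
- `examples/` — one short narrative script per capability
- `tests/` — pytest suite, including brute-force oracle checks of every
  formula and an end-to-end acceptance suite
- `docs/methods.md` — model, assumptions, numerical choices, limitations
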