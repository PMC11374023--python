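"""The full pipeline: preprocessing, fusion, joint GCN-MME training, and
5-fold cross-validated evaluation on the reference synthetic design.

This is the headline computation: 300 patients, 3 classes, three
modalities each missing 20% of patients.
"""

import psnfuse as pf

spec = pf.GeneratorSpec.default(seed=7)
matrices, labels, _ = pf.generate_multiomics(spec)

cfg = pf.RunConfig(
    modalities=[dict(name="mrna", data_kind="counts"),
                dict(name="dnam", data_kind="beta"),
                dict(name="protein", data_kind="continuous")],
    seed=7)

result = pf.run_pipeline(matrices, labels, cfg)

print("selected features per modality:",
      {p.matrix.modality_name: p.matrix.n_features for p in result.prepared})
print(f"fused graph: {result.graph.n_nodes} patients")
print(f"accuracy    {result.cv.accuracy_mean:.3f} +/- {result.cv.accuracy_sd:.3f}")
print(f"weighted F1 {result.cv.f1_mean:.3f} +/- {result.cv.f1_sd:.3f}")
for name, stats in result.cv.folds[0].per_class.items():
    print(f"  fold 0, class {name}: F1 {stats['f1']:.3f}, AUC {stats['auc']:.3f}")
# Mean +/- population SD over the 5 test folds. Every patient is
# classified, including the 20% imputed in each modality.
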