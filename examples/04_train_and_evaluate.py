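"""Train two classifier variants on a phantom cohort and compare them.

Voxels are split 8:1:1 by whole lesions (no lesion straddles the test
boundary), a 10-layer/100-node network is trained per feature set, and the
test set is scored with one-vs-rest ROC/PR analysis. Expect the
spectrum-imaging variant to beat the conventional-MRI variant by a wide
margin: its restricted/hindered/free-water split carries the pathology
signal that T1/T2 intensities alone cannot.
"""

import numpy as np

import dbsidnn as dd

cohort = dd.generate_cohort(seed=5, size_scale=0.1)
table = cohort.feature_table()
labels = table["lesion_class"].to_numpy()
parts = dd.grouped_split(table["lesion_id"].to_numpy(), labels, seed=5)
print(f"{len(parts.train_idx)} train / {len(parts.val_idx)} val / {len(parts.test_idx)} test voxels")

for variant in ("DBSI", "cMRI"):
    features = dd.build_features(table, variant)
    config = dd.DnnConfig(feature_variant=variant, seed=5, max_epochs=40)
    model = dd.train(config, parts, features, labels)
    probs = dd.predict_proba(model, features[parts.test_idx])
    report = dd.evaluate_predictions(labels[parts.test_idx], probs)
    print(f"\n=== {variant} variant ===")
    print(report.to_text())

print("\nThe per-class ROC/PR AUCs quantify one-vs-rest discrimination; the "
      "error-rate CI is an exact binomial interval on the test voxels.")
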