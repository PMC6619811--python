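"""Train the one-vs-one linear SVM on HOG features of synthetic crops.

Seven shape families (one per plankton class) are generated with known
labels, HOG descriptors are extracted, 21 pairwise linear classifiers are
trained with probability calibration, and the held-out quarter is scored.
"""

import numpy as np

from planktonseg import evaluate, extract_features, train_ovo_svm
from planktonseg.synthetic import make_labeled_dataset

counts = {c: 64 for c in ("chaetognatha", "copepoda", "medusae", "euphausiids",
                          "fish_larvae", "limacina", "other")}
samples, _ = make_labeled_dataset(counts, seed=5)
labels = np.array([s.label for s in samples])
X = extract_features([s.crop for s in samples], "hog")

train_idx, test_idx = [], []
for c in sorted(set(labels)):
    idx = np.flatnonzero(labels == c)
    train_idx.extend(idx[:48])
    test_idx.extend(idx[48:])

ens = train_ovo_svm(X[train_idx], labels[train_idx], seed=0)
rep = evaluate(ens, X[test_idx], labels[test_idx])
print(f"classes: {len(ens.classes)}, pairwise classifiers: {len(ens.pairs)}")
print(f"macro precision: {rep.macro_precision:.4f}")
print(f"macro recall:    {rep.macro_recall:.4f}")
print("confusion matrix (rows = true class):")
print(rep.confusion)
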