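"""Classify synthetic cells with Fuzzy k-NN and inspect membership values.

Fits the classifier on extracted features of a small 7-class synthetic
set, then prints the class memberships of one held-out query: the fuzzy
memberships grade how confidently each class claims the cell.
"""

import numpy as np

from qfuzzy import CLASS_NAMES, FuzzyKNN, extract_table, generate_dataset

cells, labels = generate_dataset({name: 12 for name in CLASS_NAMES}, seed=3)
table = extract_table(cells, labels)
X = table.drop(columns=["cell_id", "label"]).to_numpy()
y = np.array([CLASS_NAMES.index(l) for l in labels])

train, test = np.arange(len(y)) % 4 != 0, np.arange(len(y)) % 4 == 0
model = FuzzyKNN(k=4, m=2.0).fit(X[train], y[train])
accuracy = (model.predict(X[test]) == y[test]).mean()
print(f"hold-out accuracy on {test.sum()} cells: {accuracy:.2f}")

u = model.predict_memberships(X[test][:1])[0]
print("\nmemberships of the first held-out cell (true class: "
      f"{CLASS_NAMES[y[test][0]]}):")
for name, value in zip(CLASS_NAMES, u):
    print(f"  {name:24s} {value:.3f}")
print("rows sum to 1; the argmax is the predicted class.")
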