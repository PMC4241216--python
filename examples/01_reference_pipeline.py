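"""End-to-end analysis of the bundled Franco-Italian sarcoma cost matrix.

Runs the full chain — standardize, model-selection scan, validity profile,
PCA — and prints the headline numbers.  The cophenetic coefficient says how
faithfully the selected dendrogram preserves the object distances (1 is
perfect); the suggested k is where the pseudo-F curve peaks; the inertia
percentages say how much between-object variability the leading principal
axes capture.
"""

import costvar as cv

matrix = cv.load_sarcoma_matrix()
X = cv.standardize(matrix)

scan = cv.scan_combinations(X)
print(f"best combination: {scan.best_linkage} linkage + {scan.best_metric} "
      f"distance (c = {scan.best_coefficient:.5f})")

profile = cv.validity_profile(scan.best_tree, X)
print(f"pseudo-F suggests k = {profile.suggested_k} clusters")

labels = cv.cut(scan.best_tree, profile.suggested_k)
for lab in sorted(set(labels)):
    members = [name for name, l in zip(scan.best_tree.labels, labels) if l == lab]
    print(f"  cluster {lab}: {', '.join(members)}")

pca = cv.fit_pca(X)
print(f"cumulative inertia: 2 axes {pca.cumulative_inertia(2):.2f}%, "
      f"3 axes {pca.cumulative_inertia(3):.2f}%")
print(f"Kaiser retention (eigenvalues > 1): {pca.kaiser_count()}")
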