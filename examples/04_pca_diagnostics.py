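"""PCA interpretive statistics: contributions, qualities, correlation circle.

CTR says how much an object (or area) contributes to an axis's inertia;
cos2 how well an axis represents an area; r_j how far an area sits from the
origin of the first factorial plane — areas with r_j >= 0.8 are the ones a
two-axis reading can be trusted for.
"""

import costvar as cv

X = cv.standardize(cv.load_sarcoma_matrix())
pca = cv.fit_pca(X)

print("eigenvalues (correlation scale):", pca.eigenvalues[:6].round(3))
print(f"Kaiser retention: {pca.kaiser_count()} axes\n")

for axis in (1, 2):
    ctr = cv.ctr_individuals(pca, axis).sort_values(ascending=False)
    print(f"axis {axis}: strongest objects "
          f"{', '.join(f'{n} ({v:.0%})' for n, v in ctr.head(3).items())}")

circle = cv.correlation_circle(pca)
print("\nareas by representation quality on the first plane (r_j):")
print(circle.round(3).head(8))
print(f"\nwell represented (r_j >= 0.8): {', '.join(circle[circle.flagged].index)}")
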