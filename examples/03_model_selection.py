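"""The 15-combination metric x linkage scan, in full.

Each candidate dendrogram is scored by the cophenetic correlation between
the original pairwise distances and the heights at which the tree joins
each pair of objects.  Higher is better; the winning pair is the tree the
rest of the analysis uses.
"""

import costvar as cv

X = cv.standardize(cv.load_sarcoma_matrix())
scan = cv.scan_combinations(X)

table = scan.table.pivot(index="linkage", columns="metric", values="coefficient")
print("cophenetic correlation by combination:")
print(table.round(5))
print(f"\nbest pair: ({scan.best_linkage}, {scan.best_metric}) "
      f"with c = {scan.best_coefficient:.5f}")
print("note: Mahalanobis uses a pseudo-inverse here (12 objects x 16 areas"
      " makes the sample covariance singular)")
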