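"""Render the figures: dendrogram, validity curves, factor maps, 3-D tree.

The 3-D view overlays the selected dendrogram on the first factorial plane:
leaves sit at their principal-component coordinates, internal nodes at the
centers of gravity of their members, raised to the merge height — showing
at a glance whether the clusters are separated in the plane that carries
most of the variability.  Output goes to ./example_figures/.
"""

from pathlib import Path

import costvar as cv
from costvar import plots

outdir = Path("example_figures")
outdir.mkdir(exist_ok=True)

X = cv.standardize(cv.load_sarcoma_matrix())
scan = cv.scan_combinations(X)
profile = cv.validity_profile(scan.best_tree, X)
pca = cv.fit_pca(X)
view = cv.embed_tree(scan.best_tree, pca, profile.suggested_k)

plots.plot_dendrogram(scan.best_tree, outdir / "dendrogram.svg")
plots.plot_validity_profile(profile, outdir / "validity.svg")
plots.plot_correlation_circle(pca, outdir / "correlation_circle.svg")
plots.plot_object_map(pca, outdir / "object_map.svg", labels=view.labels)
plots.plot_hcpc_tree(view, outdir / "hcpc_tree.svg")

report = cv.interpretation_report(scan, profile, pca, view)
(outdir / "report.md").write_text(report.to_markdown())
print(f"wrote 5 figures and report.md to {outdir}/")
print(report.to_markdown())
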