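"""End-to-end pipeline: build -> standardize -> scan -> validity -> PCA -> HCPC."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as cio
from .cluster import agglomerate, scan_combinations
from .distances import compute_distances
from .hcpc import embed_tree, interpretation_report
from .model import build_matrix, standardize
from .pca import fit_pca
from .simulate import default_config, generate_patients, load_sarcoma_matrix
from .validity import validity_profile

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("costvar")


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Exactly one input source must be given: ``matrix_path`` (a labelled
    object x area CSV), ``records_path`` + ``costs_path`` (patient-level
    data), or ``fixture=True`` for the bundled reference matrix.
    """

    matrix_path: str | None = None
    records_path: str | None = None
    costs_path: str | None = None
    fixture: bool = False
    metric: str = "scan"        # a metric name, or "scan" for model selection
    linkage: str = "scan"
    k: int | str = "auto"
    n_axes: int = 2
    cost_mode: str = "simple"
    outdir: str = "costvar_output"
    seed: int = 0
    figures: bool = True

    def input_mode(self) -> str:
        sources = [
            self.matrix_path is not None,
            self.records_path is not None or self.costs_path is not None,
            self.fixture,
        ]
        if sum(sources) != 1:
            raise ValueError(
                "exactly one input source (matrix CSV, records+costs CSV, or "
                "the bundled fixture) must be selected"
            )
        if self.records_path is not None and self.costs_path is None:
            raise ValueError("records input requires a unit-cost CSV as well")
        if self.matrix_path is not None:
            return "matrix"
        if self.fixture:
            return "fixture"
        return "records"


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all artifacts under ``config.outdir``.

    Returns a dictionary with the key results (best pair, suggested k,
    memberships, inertia) and the artifact paths.  Inputs are validated
    before anything is written, so a bad path leaves no partial output.
    """
    mode = config.input_mode()
    if mode == "matrix":
        matrix = cio.read_matrix_csv(config.matrix_path)
    elif mode == "fixture":
        matrix = load_sarcoma_matrix()
    else:
        records = cio.read_records_csv(config.records_path)
        costs = cio.read_unit_costs_csv(config.costs_path)
        matrix = build_matrix(records, costs, cost_mode=config.cost_mode)
    log.info("matrix A: %d objects x %d areas", *matrix.shape)

    X = standardize(matrix)
    if config.metric == "scan" or config.linkage == "scan":
        scan = scan_combinations(X)
        log.info(
            "model selection: best pair (%s, %s), c = %.5f",
            scan.best_linkage, scan.best_metric, scan.best_coefficient,
        )
    else:
        from .cluster import CombinationScan, cophenetic_coefficient, cophenetic_distances
        import pandas as pd

        D = compute_distances(X, config.metric)
        tree = agglomerate(D, config.linkage, X=X)
        c = cophenetic_coefficient(D.condensed(), cophenetic_distances(tree))
        scan = CombinationScan(
            table=pd.DataFrame(
                [{"metric": config.metric, "linkage": config.linkage, "coefficient": c}]
            ),
            best_metric=config.metric,
            best_linkage=config.linkage,
            best_coefficient=c,
            trees={(config.metric, config.linkage): tree},
        )
    tree = scan.best_tree

    profile = validity_profile(tree, X)
    k = profile.suggested_k if config.k == "auto" else int(config.k)
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k = {k} out of range for {tree.n_leaves} objects")
    log.info("validity profile: suggested k = %d (using k = %d)", profile.suggested_k, k)

    pca = fit_pca(X)
    view = embed_tree(tree, pca, k)
    report = interpretation_report(scan, profile, pca, view, n_axes=config.n_axes)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _p(name):
        paths[name] = str(outdir / name)
        return outdir / name

    cio.write_matrix_csv(matrix, _p("matrix_A.csv"))
    cio.write_matrix_csv(X.frame, _p("matrix_X.csv"))
    cio.write_frame_csv(scan.table, _p("cophenetic_scan.csv"))
    cio.write_tree_json(tree, _p("tree.json"))
    _p("tree.nwk").write_text(tree.to_newick() + "\n")
    cio.write_frame_csv(profile.table, _p("validity_profile.csv"), index_label="k")
    cio.write_frame_csv(pca.psi, _p("pca_individuals.csv"), index_label="object")
    cio.write_frame_csv(pca.phi, _p("pca_variables.csv"), index_label="area")
    cio.write_frame_csv(
        pca.correlation_circle(), _p("correlation_circle.csv"), index_label="area"
    )
    _p("report.json").write_text(report.to_json() + "\n")
    _p("report.md").write_text(report.to_markdown())
    if config.figures:
        from . import plots

        plots.plot_dendrogram(tree, _p("dendrogram.svg"))
        plots.plot_validity_profile(profile, _p("validity.svg"))
        plots.plot_correlation_circle(pca, _p("correlation_circle.svg"))
        plots.plot_object_map(pca, _p("object_map.svg"), labels=view.labels)
        plots.plot_hcpc_tree(view, _p("hcpc_tree.svg"))

    return {
        "best_metric": scan.best_metric,
        "best_linkage": scan.best_linkage,
        "best_coefficient": scan.best_coefficient,
        "suggested_k": profile.suggested_k,
        "k": k,
        "labels": {l: int(c) for l, c in zip(tree.labels, view.labels)},
        "cumulative_inertia_2": pca.cumulative_inertia(2),
        "cumulative_inertia_3": pca.cumulative_inertia(3),
        "kaiser_count": pca.kaiser_count(),
        "artifacts": paths,
    }


def simulate_to_csv(outdir: str | Path, seed: int = 0) -> dict:
    """Generate a default synthetic cohort and write the two input CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = default_config(seed=seed)
    records, costs = generate_patients(cfg)
    rec_path = outdir / "patients.csv"
    cost_path = outdir / "unit_costs.csv"
    records.to_csv(rec_path, index=False, float_format="%.12g")
    cio.write_unit_costs_csv(costs, cost_path)
    return {"records": str(rec_path), "costs": str(cost_path), "n_rows": len(records)}
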