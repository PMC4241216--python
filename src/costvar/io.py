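"""CSV / YAML / JSON input and output for pipeline artifacts."""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cluster import MergeTree
from .model import UnitCostTable, VariabilityMatrix

__all__ = [
    "MatrixParseError",
    "read_matrix_csv",
    "write_matrix_csv",
    "read_records_csv",
    "read_unit_costs_csv",
    "write_tree_json",
    "write_frame_csv",
    "load_yaml_config",
]

_COMMA_DECIMAL = re.compile(r"^\s*-?\d+,\d+\s*$")


class MatrixParseError(ValueError):
    """Malformed matrix CSV (ragged rows, non-numeric or locale-formatted cells)."""


def read_matrix_csv(path: str | Path) -> VariabilityMatrix:
    """Read a labelled object x area matrix.

    The first column holds object labels, the header row area labels.
    Ragged rows, duplicate labels and non-numeric cells raise
    ``MatrixParseError`` pinpointing the offending row/column; a comma used
    as decimal separator is reported explicitly.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise MatrixParseError(f"{path}: empty file")
    header = rows[0]
    width = len(header)
    labels, data = [], []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise MatrixParseError(
                f"{path}: row {r} has {len(row)} fields, expected {width}"
            )
        labels.append(row[0])
        values = []
        for c, cell in enumerate(row[1:], start=2):
            if _COMMA_DECIMAL.match(cell):
                raise MatrixParseError(
                    f"{path}: row {r}, column {c}: {cell!r} uses a decimal "
                    "comma; use a decimal point"
                )
            try:
                values.append(float(cell))
            except ValueError:
                raise MatrixParseError(
                    f"{path}: row {r}, column {c}: non-numeric cell {cell!r}"
                ) from None
        data.append(values)
    columns = header[1:]
    if len(set(labels)) != len(labels) or len(set(columns)) != len(columns):
        raise MatrixParseError(f"{path}: duplicate row or column labels")
    frame = pd.DataFrame(data, index=labels, columns=columns)
    return VariabilityMatrix(frame)


def write_matrix_csv(matrix: VariabilityMatrix | pd.DataFrame, path: str | Path) -> None:
    """Write a labelled matrix at 12 significant digits (lossless round-trip)."""
    frame = matrix.frame if isinstance(matrix, VariabilityMatrix) else matrix
    frame.to_csv(path, float_format="%.12g", index_label="object")


def write_frame_csv(frame: pd.DataFrame, path: str | Path, index_label: str = "") -> None:
    frame.to_csv(path, float_format="%.12g", index_label=index_label or None)


def read_records_csv(path: str | Path) -> pd.DataFrame:
    """Patient-level records: patient_id, country, phase, factor, quantity[, year_offset]."""
    records = pd.read_csv(path)
    if "year_offset" not in records.columns:
        records["year_offset"] = 0
    return records


def read_unit_costs_csv(path: str | Path, discount_rate: float = 0.04) -> UnitCostTable:
    """Unit-cost table: country, factor, unit_cost columns."""
    frame = pd.read_csv(path)
    costs = {
        (str(r.country), str(r.factor)): float(r.unit_cost)
        for r in frame.itertuples()
    }
    return UnitCostTable(costs, discount_rate=discount_rate)


def write_unit_costs_csv(costs: UnitCostTable, path: str | Path) -> None:
    rows = [
        {"country": c, "factor": f, "unit_cost": v}
        for (c, f), v in sorted(costs.costs.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def write_tree_json(tree: MergeTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(tree.to_dict(), fh, indent=2)


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
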