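"""Object x area variability model for multi-country cost evaluations.

The transferability question — can a cost evaluation carried out in one
location stand in for local data in another? — is made operational here by a
nested data structure.  Individual *final factors* (a single unit cost or a
single resource count, e.g. the tariff of a chest radiograph) are grouped
into homogeneous *areas of variability* (e.g. "unit cost of imaging"), and
the areas are evaluated on *management objects*, a (phase of management,
country) pair such as "diagnosis in France".  Aggregating patient-level
records then yields a non-negative matrix ``A`` with one row per object and
one column per area; column standardization gives the matrix ``X`` on which
distances, clustering and PCA operate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "ConfigurationError",
    "FinalFactor",
    "AreaOfVariability",
    "ManagementObject",
    "UnitCostTable",
    "VariabilityMatrix",
    "StandardizedMatrix",
    "StudyConfiguration",
    "paper_configuration",
    "aggregate_quantity_area",
    "assign_cost_area",
    "build_matrix",
    "standardize",
    "discount",
    "RECORD_COLUMNS",
]

#: The six phases of management, in canonical order.
PHASES = (
    "diagnosis",
    "surgery",
    "chemotherapy",
    "radiotherapy",
    "follow-up without relapse",
    "follow-up with relapse",
)

#: Column schema for patient-level resource-use records.
RECORD_COLUMNS = ("patient_id", "country", "phase", "factor", "quantity", "year_offset")


class ConfigurationError(ValueError):
    """Inconsistent or incomplete factor/area/object configuration."""


@dataclass(frozen=True)
class FinalFactor:
    """A single price or quantity element that can differ between locations."""

    name: str
    category: str
    kind: str  # "quantity" | "unit_cost"
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("quantity", "unit_cost"):
            raise ConfigurationError(f"unknown factor kind {self.kind!r}")


@dataclass(frozen=True)
class AreaOfVariability:
    """A homogeneous group of final factors; one column of matrix A."""

    index: int
    label: str
    kind: str  # "quantity" | "unit_cost"
    members: tuple[FinalFactor, ...]
    aggregation_rule: str  # sum_then_mean | mean_cost_if_used | direct_if_used

    def __post_init__(self) -> None:
        if self.kind not in ("quantity", "unit_cost"):
            raise ConfigurationError(f"unknown area kind {self.kind!r}")
        if not self.members:
            raise ConfigurationError(f"area {self.label!r} has no member factors")


@dataclass(frozen=True)
class ManagementObject:
    """A (phase, country) pair; one row of matrix A."""

    index: int
    phase: str
    country: str

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ConfigurationError(
                f"unknown phase {self.phase!r}; expected one of {PHASES}"
            )

    @property
    def label(self) -> str:
        return f"{self.phase.capitalize()} {self.country}"


@dataclass
class UnitCostTable:
    """Per-country average unit costs (2009 EUR) for every final factor.

    ``costs`` maps ``(country, factor_name)`` to a non-negative unit cost.
    ``discount_rate`` is the annual discount rate applied to amounts
    incurred after the year of diagnosis.
    """

    costs: dict[tuple[str, str], float]
    discount_rate: float = 0.04

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount_rate < 1.0:
            raise ConfigurationError("discount rate must lie in [0, 1)")
        for key, value in self.costs.items():
            if value < 0:
                raise ConfigurationError(f"negative unit cost for {key}")

    def get(self, country: str, factor: str) -> float:
        try:
            return self.costs[(country, factor)]
        except KeyError:
            raise ConfigurationError(
                f"missing unit cost for factor {factor!r} in {country!r}"
            ) from None


@dataclass
class VariabilityMatrix:
    """The m x n non-negative object-by-area matrix A."""

    frame: pd.DataFrame
    objects: tuple[ManagementObject, ...] | None = None
    areas: tuple[AreaOfVariability, ...] | None = None

    def __post_init__(self) -> None:
        self.frame = self.frame.astype(float)
        if (self.frame.values < 0).any():
            raise ConfigurationError("matrix A must be non-negative")
        if self.frame.index.duplicated().any() or self.frame.columns.duplicated().any():
            raise ConfigurationError("duplicate row or column labels in matrix A")

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape


@dataclass
class StandardizedMatrix:
    """Column-standardized matrix X (population mean 0, population s.d. 1)."""

    frame: pd.DataFrame
    col_means: pd.Series
    col_sds: pd.Series

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape


@dataclass(frozen=True)
class StudyConfiguration:
    """Complete factor/area/object configuration."""

    factors: tuple[FinalFactor, ...]
    areas: tuple[AreaOfVariability, ...]
    objects: tuple[ManagementObject, ...]

    def __post_init__(self) -> None:
        seen = set()
        for f in self.factors:
            key = (f.category, f.kind, f.name)
            if key in seen:
                raise ConfigurationError(f"duplicate final factor {key}")
            seen.add(key)
        assignment: dict[tuple[str, str], int] = {}
        for area in self.areas:
            for f in area.members:
                key = (f.name, f.kind)
                if key in assignment:
                    raise ConfigurationError(
                        f"factor {f.name!r} ({f.kind}) assigned to two areas"
                    )
                assignment[key] = area.index
        pairs = {(o.phase, o.country) for o in self.objects}
        if len(pairs) != len(self.objects):
            raise ConfigurationError("duplicate (phase, country) object")

    def quantity_area_for(self, cost_area: AreaOfVariability) -> AreaOfVariability:
        """The quantity area paired with a unit-cost area (same category)."""
        category = cost_area.members[0].category
        for area in self.areas:
            if area.kind == "quantity" and area.members[0].category == category:
                return area
        raise ConfigurationError(f"no quantity area paired with {cost_area.label!r}")


_CATEGORY_FACTORS: dict[str, list[str]] = {
    "biopsies": ["surgical biopsy", "micro-biopsy", "needle aspiration cytology"],
    "hospital admissions": ["inpatient day", "outpatient day"],
    "imaging": [
        "chest radiograph",
        "colonoscopy",
        "computed tomography",
        "ultrasound",
        "magnetic resonance imaging",
    ],
    "external consultations": ["external consultation"],
    "transfusions": ["platelet pack", "red blood cell pack"],
    "radiotherapy sessions": ["radiotherapy session"],
    "radiotherapy preparation": ["radiotherapy preparation"],
    "chemotherapy drugs": [
        "caelyx",
        "carboplatin",
        "cisplatin",
        "deticene",
        "doxorubicin",
        "etoposide",
        "gemcitabine",
        "holoxan",
        "ifosfamide",
        "imatinib",
        "melphalan",
        "vinorelbine",
        "oxaliplatin",
        "paclitaxel",
        "vincristine",
    ],
}

_AREA_SHORT = {
    "biopsies": "biopsies",
    "hospital admissions": "hospital days",
    "imaging": "imaging",
    "external consultations": "external consultations",
    "transfusions": "transfusions",
    "radiotherapy sessions": "radiotherapy sessions",
    "radiotherapy preparation": "radiotherapy preparation",
    "chemotherapy drugs": "chemotherapy drugs",
}


def paper_configuration(countries: Sequence[str] = ("France", "Italy")) -> StudyConfiguration:
    """The 60-factor / 16-area / 12-object configuration of the sarcoma study.

    Eight resource categories, each contributing a quantity area and a
    unit-cost area (8 x 2 = 16 areas); six phases of management crossed with
    the given countries (6 x 2 = 12 objects).
    """
    factors: list[FinalFactor] = []
    areas: list[AreaOfVariability] = []
    categories = list(_CATEGORY_FACTORS)
    for kind_offset, kind in ((0, "quantity"), (8, "unit_cost")):
        for i, category in enumerate(categories):
            members = tuple(
                FinalFactor(name=n, category=category, kind=kind)
                for n in _CATEGORY_FACTORS[category]
            )
            factors.extend(members)
            if kind == "quantity":
                rule = "sum_then_mean"
                label = f"Q {_AREA_SHORT[category]}"
            else:
                rule = "mean_cost_if_used" if len(members) > 1 else "direct_if_used"
                label = f"C {_AREA_SHORT[category]}"
            areas.append(
                AreaOfVariability(
                    index=kind_offset + i + 1,
                    label=label,
                    kind=kind,
                    members=members,
                    aggregation_rule=rule,
                )
            )
    objects = tuple(
        ManagementObject(index=2 * p + c + 1, phase=phase, country=country)
        for p, phase in enumerate(PHASES)
        for c, country in enumerate(countries)
    )
    return StudyConfiguration(tuple(factors), tuple(areas), tuple(objects))


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS[:5] if c not in records.columns]
    if missing:
        raise ConfigurationError(f"patient records lack columns {missing}")
    bad = set(records["phase"]) - set(PHASES)
    if bad:
        raise ConfigurationError(f"unknown phase label(s) {sorted(bad)}")
    if (records["quantity"] < 0).any():
        raise ConfigurationError("negative resource quantity in records")
    return records


def aggregate_quantity_area(
    records: pd.DataFrame,
    obj: ManagementObject,
    area: AreaOfVariability,
) -> float:
    """Mean, over the object's patients, of the per-patient sum of the
    area's member factors.  Returns 0 when no patient visited the phase."""
    if area.kind != "quantity":
        raise ConfigurationError(f"{area.label!r} is not a quantity area")
    records = _check_records(records)
    sub = records[(records["country"] == obj.country) & (records["phase"] == obj.phase)]
    if sub.empty:
        return 0.0
    member_names = {f.name for f in area.members}
    patients = sub["patient_id"].unique()
    in_area = sub[sub["factor"].isin(member_names)]
    total = float(in_area["quantity"].sum())
    return total / len(patients)


def assign_cost_area(
    costs: UnitCostTable,
    obj: ManagementObject,
    area: AreaOfVariability,
    paired_quantity: float,
    usage: Mapping[str, float] | None = None,
    mode: str = "simple",
    discount_factor: float = 1.0,
) -> float:
    """Country mean unit cost of the area's member factors, applied only to
    objects that actually use the resource (``paired_quantity > 0``).

    ``mode="simple"`` takes the unweighted mean over member factors;
    ``mode="usage_weighted"`` weights each member cost by the object's usage
    of that factor (falling back to the simple mean when usage is absent).
    """
    if area.kind != "unit_cost":
        raise ConfigurationError(f"{area.label!r} is not a unit-cost area")
    if mode not in ("simple", "usage_weighted"):
        raise ConfigurationError(f"unknown cost aggregation mode {mode!r}")
    if paired_quantity <= 0:
        return 0.0
    member_costs = {f.name: costs.get(obj.country, f.name) for f in area.members}
    if mode == "usage_weighted" and usage:
        weights = {n: float(usage.get(n, 0.0)) for n in member_costs}
        wsum = sum(weights.values())
        if wsum > 0:
            value = sum(member_costs[n] * w for n, w in weights.items()) / wsum
            return value * discount_factor
    return (sum(member_costs.values()) / len(member_costs)) * discount_factor


def build_matrix(
    records: pd.DataFrame,
    costs: UnitCostTable,
    config: StudyConfiguration | None = None,
    cost_mode: str = "simple",
    apply_discount: bool = False,
) -> VariabilityMatrix:
    """Aggregate patient-level records into matrix A.

    Quantity areas hold the mean per-patient sum of their member factors;
    unit-cost areas hold the country mean unit cost, zeroed for objects
    whose paired quantity area is zero.  With ``apply_discount=True`` each
    cost cell is multiplied by the object's mean present-value factor,
    computed from the records' ``year_offset`` column, so the matrix holds
    already-discounted means.
    """
    if config is None:
        config = paper_configuration()
    records = _check_records(records)
    known_countries = {o.country for o in config.objects}
    bad = set(records["country"]) - known_countries
    if bad:
        raise ConfigurationError(f"unknown country label(s) {sorted(bad)}")

    rows = []
    for obj in config.objects:
        sub = records[
            (records["country"] == obj.country) & (records["phase"] == obj.phase)
        ]
        quantities = {
            area.index: aggregate_quantity_area(records, obj, area)
            for area in config.areas
            if area.kind == "quantity"
        }
        if apply_discount and "year_offset" in sub.columns and not sub.empty:
            offsets = sub.groupby("patient_id")["year_offset"].max()
            dfac = float(
                np.mean([discount(1.0, int(y), costs.discount_rate) for y in offsets])
            )
        else:
            dfac = 1.0
        row = {}
        for area in config.areas:
            if area.kind == "quantity":
                row[area.label] = quantities[area.index]
            else:
                paired = config.quantity_area_for(area)
                member_names = {f.name for f in area.members}
                usage = (
                    sub[sub["factor"].isin({f.name for f in paired.members})]
                    .groupby("factor")["quantity"]
                    .sum()
                    .to_dict()
                )
                # usage keys are quantity-factor names; cost members mirror them
                usage = {n: usage.get(n, 0.0) for n in member_names} if usage else None
                row[area.label] = assign_cost_area(
                    costs,
                    obj,
                    area,
                    quantities[paired.index],
                    usage=usage,
                    mode=cost_mode,
                    discount_factor=dfac,
                )
        rows.append(pd.Series(row, name=obj.label))
    frame = pd.DataFrame(rows)
    frame = frame[[a.label for a in config.areas]]
    return VariabilityMatrix(frame, objects=config.objects, areas=config.areas)


def standardize(matrix: VariabilityMatrix | pd.DataFrame) -> StandardizedMatrix:
    """Column-standardize A to X using the population (1/m) standard deviation.

    Raises ``ConfigurationError`` naming the offending column when a column
    has zero variance (non-varying factors must be excluded upstream).
    """
    frame = matrix.frame if isinstance(matrix, VariabilityMatrix) else pd.DataFrame(matrix)
    frame = frame.astype(float)
    means = frame.mean(axis=0)
    sds = frame.std(axis=0, ddof=0)  # population denominator, 1/m
    zero = sds[sds == 0.0]
    if not zero.empty:
        raise ConfigurationError(
            f"zero-variance column(s) {list(zero.index)}: non-varying areas "
            "must be removed before standardization"
        )
    X = (frame - means) / sds
    return StandardizedMatrix(X, col_means=means, col_sds=sds)


def discount(amount: float, years: int, rate: float = 0.04) -> float:
    """Present value of ``amount`` incurred ``years`` after diagnosis."""
    if years < 0:
        raise ValueError("years must be non-negative")
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    return amount / (1.0 + rate) ** years
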