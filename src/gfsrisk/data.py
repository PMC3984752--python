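"""Clinical dataset model and file I/O.

A cohort is a flat table: one row per patient case, one column per feature,
plus an optional physician risk label.  Features are declared in a schema as
either *numerical* (real-valued, with observed [min, max] bounds filled in at
load time) or *categorical* (a finite token domain such as ``{yes, no}``).
Risk labels form a three-level ordinal scale: low-risk < medium-risk <
high-risk.

Missing values are permitted and represented explicitly as ``None``; they are
never imputed.  Downstream fuzzy machinery treats a missing value as having
membership zero in every fuzzy set.
"""

from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class SchemaError(ValueError):
    """Raised for malformed or inconsistent feature schemas."""


class DataLoadError(ValueError):
    """Raised when a data file does not conform to its schema."""


class RiskLabel(enum.Enum):
    """Ordinal unstable-angina risk level assigned by a physician."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2

    @property
    def rank(self) -> int:
        return self.value

    @property
    def level(self) -> str:
        return {0: "low-risk", 1: "medium-risk", 2: "high-risk"}[self.value]

    @classmethod
    def parse(cls, token: str) -> "RiskLabel":
        t = str(token).strip().lower()
        for suffix in ("-risk", " risk", "_risk"):
            if t.endswith(suffix):
                t = t[: -len(suffix)]
        try:
            return {"low": cls.LOW, "medium": cls.MEDIUM, "high": cls.HIGH}[t]
        except KeyError:
            raise ValueError(f"unknown risk label: {token!r}") from None

    def __lt__(self, other: "RiskLabel") -> bool:
        return self.value < other.value


#: The three levels in increasing-risk order.
RISK_LEVELS: tuple[RiskLabel, ...] = (RiskLabel.LOW, RiskLabel.MEDIUM, RiskLabel.HIGH)


def _norm_token(tok: str) -> str:
    return str(tok).strip().lower()


@dataclass
class FeatureSchema:
    """Declaration of one patient feature.

    Parameters
    ----------
    name : str
        Unique feature identifier.
    kind : {"numerical", "categorical"}
    domain : list
        For categorical features, the finite token list (non-empty,
        duplicate-free after case-folding).  For numerical features the
        observed ``[min, max]`` bounds, or ``None`` until a dataset has been
        loaded.
    """

    name: str
    kind: str
    domain: list | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("numerical", "categorical"):
            raise SchemaError(f"feature {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.domain:
                raise SchemaError(f"feature {self.name!r}: empty categorical domain")
            normed = [_norm_token(t) for t in self.domain]
            if len(set(normed)) != len(normed):
                raise SchemaError(f"feature {self.name!r}: duplicate domain tokens")
            self.domain = [str(t) for t in self.domain]
        elif self.domain is not None:
            lo, hi = self.domain
            if not (float(lo) <= float(hi)):
                raise SchemaError(f"feature {self.name!r}: min > max in bounds")
            self.domain = [float(lo), float(hi)]

    @property
    def is_numerical(self) -> bool:
        return self.kind == "numerical"

    def domain_index(self, token: str) -> int:
        """Position of a categorical token in the domain (case-insensitive)."""
        normed = [_norm_token(t) for t in self.domain]
        try:
            return normed.index(_norm_token(token))
        except ValueError:
            raise DataLoadError(
                f"token {token!r} not in domain of feature {self.name!r}"
            ) from None


@dataclass
class PatientCase:
    """One clinical record: feature values plus an optional physician label."""

    id: str
    values: dict
    label: RiskLabel | None = None

    def get(self, feature: str):
        return self.values.get(feature)


@dataclass
class Dataset:
    """An ordered collection of patient cases validated against a schema."""

    schema: list[FeatureSchema]
    cases: list[PatientCase] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [f.name for f in self.schema]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names in schema")
        for case in self.cases:
            self._validate_case(case)
        self._update_bounds()

    def _validate_case(self, case: PatientCase) -> None:
        by_name = {f.name: f for f in self.schema}
        for name, value in case.values.items():
            if name not in by_name:
                raise DataLoadError(f"case {case.id}: unknown feature {name!r}")
            if value is None:
                continue
            feat = by_name[name]
            if feat.is_numerical:
                if not isinstance(value, (int, float)) or math.isnan(float(value)):
                    raise DataLoadError(
                        f"case {case.id}: non-numeric value {value!r} "
                        f"for numerical feature {name!r}"
                    )
            else:
                feat.domain_index(value)  # raises if outside domain

    def _update_bounds(self) -> None:
        for feat in self.schema:
            if not feat.is_numerical:
                continue
            vals = [
                float(c.values[feat.name])
                for c in self.cases
                if c.values.get(feat.name) is not None
            ]
            if vals:
                feat.domain = [min(vals), max(vals)]

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.schema]

    def feature(self, name: str) -> FeatureSchema:
        for f in self.schema:
            if f.name == name:
                return f
        raise KeyError(name)

    def numerical_values(self, name: str) -> list[float]:
        """All non-missing values of a numerical feature, in row order."""
        feat = self.feature(name)
        if not feat.is_numerical:
            raise SchemaError(f"feature {name!r} is not numerical")
        return [
            float(c.values[name]) for c in self.cases if c.values.get(name) is not None
        ]

    def labels(self) -> list[RiskLabel]:
        out = []
        for c in self.cases:
            if c.label is None:
                raise DataLoadError(f"case {c.id} is unlabelled")
            out.append(c.label)
        return out

    def subset(self, indices: Sequence[int]) -> "Dataset":
        """New dataset sharing the schema declarations but re-derived bounds."""
        schema = [
            FeatureSchema(f.name, f.kind, None if f.is_numerical else list(f.domain))
            for f in self.schema
        ]
        cases = [
            PatientCase(self.cases[i].id, dict(self.cases[i].values), self.cases[i].label)
            for i in indices
        ]
        return Dataset(schema, cases)


def class_counts(d: Dataset) -> dict[RiskLabel, int]:
    """Count labelled cases per risk level; every case must be labelled."""
    counts = {lvl: 0 for lvl in RISK_LEVELS}
    for label in d.labels():
        counts[label] += 1
    return counts


# ---------------------------------------------------------------------------
# File I/O: JSON schema documents and RFC-4180 CSV cohorts.

def load_schema(path) -> list[FeatureSchema]:
    """Read a JSON schema document: a list of {"name", "kind", "domain"}."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed schema document {path}: {exc}") from exc
    if not isinstance(doc, list):
        raise SchemaError(f"schema document {path} must be a JSON list")
    schema: list[FeatureSchema] = []
    seen: set[str] = set()
    for entry in doc:
        if not isinstance(entry, dict) or "name" not in entry or "kind" not in entry:
            raise SchemaError(f"schema entry missing name/kind: {entry!r}")
        name = str(entry["name"])
        if name in seen:
            raise SchemaError(f"duplicate feature name {name!r}")
        seen.add(name)
        schema.append(FeatureSchema(name, entry["kind"], entry.get("domain")))
    return schema


def save_schema(schema: Iterable[FeatureSchema], path) -> None:
    doc = []
    for f in schema:
        entry: dict = {"name": f.name, "kind": f.kind}
        if f.kind == "categorical":
            entry["domain"] = list(f.domain)
        elif f.domain is not None:
            entry["domain"] = [float(f.domain[0]), float(f.domain[1])]
        doc.append(entry)
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def load_dataset(
    path,
    schema: list[FeatureSchema],
    label_column: str = "risk",
    id_column: str = "id",
) -> Dataset:
    """Read a CSV cohort (header row; empty fields are missing values).

    Numerical bounds on the schema are updated to the observed min/max.
    Row order is preserved.  The label column is optional; when present every
    value must parse as a risk level (or be empty for an unlabelled case).
    """
    by_name = {f.name: f for f in schema}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DataLoadError(f"{path}: empty file") from None
        for col in header:
            if col not in by_name and col not in (label_column, id_column):
                raise DataLoadError(f"{path}: unknown column {col!r}")
        cases: list[PatientCase] = []
        for rownum, row in enumerate(reader, start=2):
            if not row or all(cell.strip() == "" for cell in row):
                continue
            if len(row) != len(header):
                raise DataLoadError(f"{path} row {rownum}: wrong field count")
            values: dict = {}
            label: RiskLabel | None = None
            case_id = f"case_{len(cases) + 1}"
            for col, cell in zip(header, row):
                cell = cell.strip()
                if col == id_column:
                    if cell:
                        case_id = cell
                    continue
                if col == label_column:
                    if cell:
                        try:
                            label = RiskLabel.parse(cell)
                        except ValueError as exc:
                            raise DataLoadError(
                                f"{path} row {rownum}, column {col!r}: {exc}"
                            ) from None
                    continue
                feat = by_name[col]
                if cell == "":
                    values[col] = None
                elif feat.is_numerical:
                    try:
                        values[col] = float(cell)
                    except ValueError:
                        raise DataLoadError(
                            f"{path} row {rownum}, column {col!r}: "
                            f"non-numeric value {cell!r}"
                        ) from None
                else:
                    feat.domain_index(cell)
                    values[col] = cell
            cases.append(PatientCase(case_id, values, label))
    if not cases:
        raise DataLoadError(f"{path}: no data rows")
    return Dataset(schema, cases)


def save_dataset(
    d: Dataset, path, label_column: str = "risk", id_column: str = "id"
) -> None:
    """Write a cohort back to CSV; round-trips exactly through load_dataset."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        header = [id_column] + d.feature_names + [label_column]
        writer.writerow(header)
        for case in d.cases:
            row = [case.id]
            for feat in d.schema:
                v = case.values.get(feat.name)
                if v is None:
                    row.append("")
                elif feat.is_numerical:
                    fv = float(v)
                    row.append(repr(int(fv)) if fv == int(fv) else repr(fv))
                else:
                    row.append(str(v))
            row.append(case.label.level if case.label is not None else "")
            writer.writerow(row)
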