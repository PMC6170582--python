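"""Specimen records, per-element datasets, and CSV readers/writers.

A specimen table is a wide CSV, one bone per row: ``specimen_id`` and
``element`` are required, ``collection``, ``locality``, ``type_taxon``,
``type_year``, ``type_month`` and ``type_role`` are optional metadata, and
the remaining columns named by measurement codes hold lengths in mm.
Missing measurements are written as empty cells; both empty cells and the
literal ``NA`` are accepted on read.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scheme import Element, MeasurementScheme, get_scheme, looks_like_code

MISSING_MARKERS = ("", "NA")

META_COLUMNS = (
    "specimen_id", "element", "collection", "locality",
    "type_taxon", "type_year", "type_month", "type_role",
)

TYPE_ROLES = ("holotype", "syntype", "lectotype")


class SchemaError(ValueError):
    """A column claims to be a measurement code that the element lacks."""


@dataclass(frozen=True)
class TypeStatus:
    """Name-bearing status of a specimen under zoological nomenclature."""

    taxon_name: str
    pub_year: int
    pub_month: int | None = None
    role: str = "holotype"

    def __post_init__(self) -> None:
        if self.role not in TYPE_ROLES:
            raise ValueError(f"unknown type role {self.role!r}")
        if self.pub_month is not None and not 1 <= self.pub_month <= 12:
            raise ValueError(f"pub_month out of range: {self.pub_month}")


@dataclass
class SpecimenRecord:
    """One measured bone: metadata plus a partially observed measurement map."""

    specimen_id: str
    element: Element
    measurements: dict[str, float]
    collection: str | None = None
    locality: str | None = None
    type_status: TypeStatus | None = None
    extra: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        scheme = get_scheme(self.element)
        valid = set(scheme.codes)
        for code, value in self.measurements.items():
            if code not in valid:
                raise SchemaError(
                    f"specimen {self.specimen_id!r}: code {code!r} is not in the "
                    f"{self.element.value} scheme"
                )
            if not math.isfinite(value) or value <= 0:
                raise ValueError(
                    f"specimen {self.specimen_id!r}, column {code!r}: "
                    f"measurement must be a positive length, got {value!r}"
                )

    @property
    def scheme(self) -> MeasurementScheme:
        return get_scheme(self.element)

    def missing_codes(self) -> list[str]:
        return [c for c in self.scheme.codes if c not in self.measurements]


def missing_fraction(record: SpecimenRecord) -> float:
    """Fraction of the element's full code list that is unobserved."""
    scheme = get_scheme(record.element)
    return len(record.missing_codes()) / scheme.n_codes


@dataclass
class Dataset:
    """All specimens of a single skeletal element.

    The matrix view is a specimens x codes DataFrame in mm with NaN marking
    missing cells; column order follows the element's measurement scheme.
    """

    element: Element
    records: list[SpecimenRecord]

    def __post_init__(self) -> None:
        for r in self.records:
            if r.element != self.element:
                raise ValueError(
                    f"record {r.specimen_id!r} is a {r.element.value}, "
                    f"dataset holds {self.element.value}"
                )
        ids = [r.specimen_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate specimen_id in dataset")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def scheme(self) -> MeasurementScheme:
        return get_scheme(self.element)

    def matrix(self) -> pd.DataFrame:
        codes = list(self.scheme.codes)
        data = np.full((len(self.records), len(codes)), np.nan)
        for i, rec in enumerate(self.records):
            for j, code in enumerate(codes):
                if code in rec.measurements:
                    data[i, j] = rec.measurements[code]
        return pd.DataFrame(
            data, index=[r.specimen_id for r in self.records], columns=codes
        )

    def missing_mask(self) -> pd.DataFrame:
        return self.matrix().isna()

    def missing_fractions(self) -> pd.Series:
        return pd.Series(
            {r.specimen_id: missing_fraction(r) for r in self.records},
            name="missing_fraction",
        )

    def subset(self, specimen_ids) -> "Dataset":
        wanted = set(specimen_ids)
        return Dataset(
            self.element, [r for r in self.records if r.specimen_id in wanted]
        )

    def record_map(self) -> dict[str, SpecimenRecord]:
        return {r.specimen_id: r for r in self.records}

    def metadata(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict[str, object] = {
                "specimen_id": r.specimen_id,
                "element": r.element.value,
                "collection": r.collection,
                "locality": r.locality,
            }
            if r.type_status is not None:
                row.update(
                    type_taxon=r.type_status.taxon_name,
                    type_year=r.type_status.pub_year,
                    type_month=r.type_status.pub_month,
                    type_role=r.type_status.role,
                )
            row.update(r.extra)
            rows.append(row)
        return pd.DataFrame(rows).set_index("specimen_id")


def _parse_type_status(row: pd.Series, specimen_id: str) -> TypeStatus | None:
    taxon = row.get("type_taxon")
    if taxon is None or (isinstance(taxon, float) and math.isnan(taxon)) or taxon == "":
        return None
    year = row.get("type_year")
    if year is None or (isinstance(year, float) and math.isnan(year)):
        raise ValueError(f"specimen {specimen_id!r}: type_taxon given without type_year")
    month = row.get("type_month")
    if month is None or (isinstance(month, float) and math.isnan(month)) or month == "":
        month_val = None
    else:
        month_val = int(month)
    role = row.get("type_role")
    if role is None or (isinstance(role, float) and math.isnan(role)) or role == "":
        role = "holotype"
    return TypeStatus(str(taxon), int(year), month_val, str(role))


def read_specimen_table(path: str | Path, element: Element | str) -> Dataset:
    """Read a wide specimen CSV into a validated Dataset.

    Unknown non-measurement columns are preserved as record metadata; a
    column that looks like a measurement code but is not in the element's
    scheme raises :class:`SchemaError`.  Rows with zero observed
    measurements are rejected.
    """
    element = Element(element)
    scheme = get_scheme(element)
    df = pd.read_csv(
        path, dtype={"specimen_id": str},
        na_values=list(MISSING_MARKERS), keep_default_na=False,
    )
    if "specimen_id" not in df.columns:
        raise SchemaError("missing required column 'specimen_id'")
    valid = set(scheme.codes)
    measurement_cols, extra_cols = [], []
    for col in df.columns:
        if col in META_COLUMNS:
            continue
        if col in valid:
            measurement_cols.append(col)
        elif looks_like_code(col):
            raise SchemaError(
                f"column {col!r} is not a measurement code of the "
                f"{element.value} scheme"
            )
        else:
            extra_cols.append(col)

    records = []
    for idx, row in df.iterrows():
        sid = str(row["specimen_id"])
        if "element" in df.columns:
            row_elem = str(row["element"])
            if row_elem and Element(row_elem) != element:
                raise SchemaError(
                    f"row {idx} (specimen {sid!r}): element {row_elem!r} "
                    f"does not match requested {element.value!r}"
                )
        meas: dict[str, float] = {}
        for code in measurement_cols:
            raw = row[code]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                continue
            try:
                value = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"row {idx} (specimen {sid!r}), column {code!r}: "
                    f"non-numeric measurement {raw!r}"
                ) from None
            if not math.isfinite(value) or value <= 0:
                raise ValueError(
                    f"row {idx} (specimen {sid!r}), column {code!r}: "
                    f"non-positive measurement {value!r}"
                )
            meas[code] = value
        if not meas:
            raise ValueError(
                f"row {idx} (specimen {sid!r}): no observed measurements"
            )
        coll = row.get("collection")
        loc = row.get("locality")
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                element=element,
                measurements=meas,
                collection=None if pd.isna(coll) else str(coll) if coll is not None else None,
                locality=None if pd.isna(loc) else str(loc) if loc is not None else None,
                type_status=_parse_type_status(row, sid),
                extra={c: row[c] for c in extra_cols if not pd.isna(row[c])},
            )
        )
    return Dataset(element, records)


def write_specimen_table(dataset: Dataset, path: str | Path) -> None:
    """Write a Dataset back to the wide CSV layout (empty cell = missing)."""
    codes = list(dataset.scheme.codes)
    rows = []
    for r in dataset.records:
        row: dict[str, object] = {
            "specimen_id": r.specimen_id,
            "element": r.element.value,
        }
        if r.collection is not None:
            row["collection"] = r.collection
        if r.locality is not None:
            row["locality"] = r.locality
        if r.type_status is not None:
            row["type_taxon"] = r.type_status.taxon_name
            row["type_year"] = r.type_status.pub_year
            if r.type_status.pub_month is not None:
                row["type_month"] = r.type_status.pub_month
            row["type_role"] = r.type_status.role
        row.update(r.extra)
        for code in codes:
            row[code] = r.measurements.get(code, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, na_rep="")


def write_results(bundle: dict, out_dir: str | Path) -> list[Path]:
    """Persist a pipeline results bundle.

    Writes ``labels.csv`` (per-specimen cluster labels, uncertainties and
    round tags), ``run_report.json`` (model family, K, BIC table, imputation
    ranks, seeds, thresholds) and ``cluster_ranges.csv`` (per-cluster
    observed measurement ranges).  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    labels = bundle.get("labels")
    if labels is None:
        raise ValueError("results bundle has no 'labels' table")
    labels_path = out_dir / "labels.csv"
    pd.DataFrame(labels).to_csv(labels_path, index=False)
    written.append(labels_path)

    report = bundle.get("report")
    if report is None:
        raise ValueError("results bundle has no 'report'")
    report_path = out_dir / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, default=_json_default))
    written.append(report_path)

    ranges = bundle.get("cluster_ranges")
    if ranges is None:
        raise ValueError("results bundle has no 'cluster_ranges' table")
    ranges_path = out_dir / "cluster_ranges.csv"
    pd.DataFrame(ranges).to_csv(ranges_path, index=False)
    written.append(ranges_path)
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Element):
        return obj.value
    raise TypeError(f"not JSON serializable: {type(obj)}")


def cluster_ranges_table(dataset: Dataset, labels: pd.Series) -> pd.DataFrame:
    """Per-cluster min-max ranges of observed values, one row per code,
    mirroring the layout of published per-taxon measurement tables."""
    matrix = dataset.matrix()
    rows = []
    for code in dataset.scheme.codes:
        row: dict[str, object] = {"code": code}
        for cluster in sorted(labels.dropna().unique(), key=str):
            members = labels.index[labels == cluster]
            vals = matrix.loc[matrix.index.intersection(members), code].dropna()
            if len(vals):
                row[f"{cluster}_min"] = vals.min()
                row[f"{cluster}_max"] = vals.max()
                row[f"{cluster}_n"] = len(vals)
        rows.append(row)
    return pd.DataFrame(rows)
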