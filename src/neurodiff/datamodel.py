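"""Core domain types, CSV readers/writers and cohort validation.

Feature tables are plain CSV: two id columns (``subject_id``, ``visit_id``)
followed by feature columns named ``<type>_<scale>_<roiId>_<patchIdx>``,
grouped into ordered blocks (volume at scales 500/1000/2000, then thickness
at the same scales).  Values round-trip at full float precision.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ID_COLUMNS = ("subject_id", "visit_id")


class Diagnosis(str, Enum):
    NC = "NC"
    AD = "AD"
    FTD = "FTD"


class Sex(str, Enum):
    M = "M"
    F = "F"


class FieldStrength(str, Enum):
    T15 = "1.5T"
    T3 = "3T"


#: canonical class ordering used everywhere downstream (labels 0, 1, 2)
CLASS_ORDER = (Diagnosis.NC, Diagnosis.AD, Diagnosis.FTD)


@dataclass(frozen=True)
class SubjectRecord:
    """Metadata for one scan (one row of a feature table).

    A subject may own several visits but must carry a single diagnosis
    across all of them; converters are flagged by :func:`validate_cohort`.
    """

    subject_id: str
    visit_id: str
    diagnosis: Diagnosis
    age: float
    sex: Sex
    icv: float
    field_strength: FieldStrength
    site: str = "site0"
    scanner: str = "scanner0"

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        if not self.age > 0:
            raise ValueError(f"age must be > 0, got {self.age}")
        if not self.icv > 0:
            raise ValueError(f"icv must be > 0, got {self.icv}")
        # allow plain strings for the enums at construction time
        for name, enum_cls in (
            ("diagnosis", Diagnosis),
            ("sex", Sex),
            ("field_strength", FieldStrength),
        ):
            value = getattr(self, name)
            if not isinstance(value, enum_cls):
                object.__setattr__(self, name, enum_cls(value))

    @property
    def label(self) -> int:
        """Integer class label in the canonical NC/AD/FTD ordering."""
        return CLASS_ORDER.index(self.diagnosis)


@dataclass(frozen=True)
class FeatureSetSpec:
    """One block of the feature table: a (type, scale) pair and its width."""

    feature_type: str  # "volume" | "thickness"
    scale: object  # "ROI" | 500 | 1000 | 2000
    dimension: int

    def __post_init__(self) -> None:
        if self.feature_type not in ("volume", "thickness"):
            raise ValueError(f"unknown feature_type {self.feature_type!r}")
        if self.scale not in ("ROI", 500, 1000, 2000):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.dimension < 1:
            raise ValueError("dimension must be positive")

    @property
    def name(self) -> str:
        return f"{self.feature_type}:{self.scale}"


#: default six feature sets; dimensions concatenate to 3,449
DEFAULT_FEATURE_SETS = (
    FeatureSetSpec("volume", 500, 1488),
    FeatureSetSpec("volume", 1000, 705),
    FeatureSetSpec("volume", 2000, 343),
    FeatureSetSpec("thickness", 500, 527),
    FeatureSetSpec("thickness", 1000, 255),
    FeatureSetSpec("thickness", 2000, 131),
)


def total_dimension(specs: Sequence[FeatureSetSpec]) -> int:
    return sum(s.dimension for s in specs)


def default_column_names(specs: Sequence[FeatureSetSpec]) -> list[str]:
    """Generic feature column names for tables without patch provenance."""
    names = []
    for spec in specs:
        names.extend(
            f"{spec.feature_type}_{spec.scale}_0_{i}" for i in range(spec.dimension)
        )
    return names


def scaled_feature_sets(fraction: float) -> tuple[FeatureSetSpec, ...]:
    """The default six blocks shrunk by ``fraction`` (for desk-scale runs)."""
    return tuple(
        FeatureSetSpec(s.feature_type, s.scale, max(1, round(s.dimension * fraction)))
        for s in DEFAULT_FEATURE_SETS
    )


class FeatureTable:
    """Subjects-by-features matrix carrying a feature-set block partition.

    Rows are (subject_id, visit_id) pairs; columns are ordered feature names
    partitioned into the blocks given by ``specs`` (in order).
    """

    def __init__(
        self,
        ids: pd.DataFrame,
        values: np.ndarray,
        columns: Sequence[str],
        specs: Sequence[FeatureSetSpec],
        kind: str = "raw",
    ):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be 2-D")
        if values.shape[1] != len(columns):
            raise ValueError(
                f"{values.shape[1]} value columns but {len(columns)} names"
            )
        if values.shape[1] != total_dimension(specs):
            raise ValueError(
                f"feature dimension {values.shape[1]} does not match spec total "
                f"{total_dimension(specs)}"
            )
        if len(ids) != values.shape[0]:
            raise ValueError("ids and values row counts differ")
        if kind not in ("raw", "wscore"):
            raise ValueError("kind must be 'raw' or 'wscore'")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))
            raise ValueError(
                f"non-finite value at row {bad[0][0]}, column {columns[bad[0][1]]}"
            )
        self.ids = ids.reset_index(drop=True)[list(ID_COLUMNS)].astype(str)
        self.values = values
        self.columns = list(columns)
        self.specs = tuple(specs)
        self.kind = kind

    # -- structure ---------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def block_slices(self) -> list[slice]:
        """Column slice of each feature-set block, in spec order."""
        out, start = [], 0
        for spec in self.specs:
            out.append(slice(start, start + spec.dimension))
            start += spec.dimension
        return out

    def block(self, i: int) -> np.ndarray:
        return self.values[:, self.block_slices()[i]]

    def column_digest(self) -> str:
        """SHA-256 over the ordered column names (ordering stability check)."""
        h = hashlib.sha256()
        for c in self.columns:
            h.update(c.encode())
            h.update(b"\0")
        return h.hexdigest()

    # -- derivation --------------------------------------------------------

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "FeatureTable":
        return FeatureTable(
            self.ids, values, self.columns, self.specs, kind or self.kind
        )

    def subset(self, row_index: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            self.ids.iloc[row_index],
            self.values[row_index],
            self.columns,
            self.specs,
            self.kind,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        return pd.concat([self.ids.reset_index(drop=True), df], axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.columns == other.columns
            and self.specs == other.specs
            and self.ids.equals(other.ids)
            and np.array_equal(self.values, other.values)
        )


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table as CSV with full float precision (repr)."""
    df = table.to_dataframe()
    df.to_csv(path, index=False, float_format=None)


def read_feature_table(
    path, specs: Sequence[FeatureSetSpec], kind: str = "raw"
) -> FeatureTable:
    """Read a CSV feature table and validate it against ``specs``.

    Raises ``ValueError`` naming the offending column for missing id
    columns, non-numeric cells, or a block-dimension mismatch.
    """
    df = pd.read_csv(
        path, dtype={c: str for c in ID_COLUMNS}, float_precision="round_trip"
    )
    for c in ID_COLUMNS:
        if c not in df.columns:
            raise ValueError(f"missing required id column {c!r}")
    feat_cols = [c for c in df.columns if c not in ID_COLUMNS]
    expected = total_dimension(specs)
    if len(feat_cols) != expected:
        raise ValueError(
            f"expected {expected} feature columns for spec, found {len(feat_cols)}; "
            f"check for missing/extra columns"
        )
    # verify the block structure encoded in the column names, in order
    start = 0
    for spec in specs:
        block_cols = feat_cols[start : start + spec.dimension]
        prefix = f"{spec.feature_type}_{spec.scale}_"
        bad = [c for c in block_cols if not c.startswith(prefix)]
        if bad:
            raise ValueError(
                f"block {spec.name} expects columns prefixed {prefix!r}; "
                f"offending column {bad[0]!r}"
            )
        start += spec.dimension
    values = np.empty((len(df), len(feat_cols)))
    for j, c in enumerate(feat_cols):
        col = pd.to_numeric(df[c], errors="coerce")
        if col.isna().any():
            row = int(col.isna().idxmax())
            raise ValueError(f"non-numeric or missing value in column {c!r} row {row}")
        values[:, j] = col.to_numpy(dtype=float)
    return FeatureTable(df[list(ID_COLUMNS)], values, feat_cols, specs, kind)


# -- metadata I/O ----------------------------------------------------------


def write_records(records: Iterable[SubjectRecord], path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "visit_id": r.visit_id,
            "diagnosis": r.diagnosis.value,
            "age": r.age,
            "sex": r.sex.value,
            "icv": r.icv,
            "field_strength": r.field_strength.value,
            "site": r.site,
            "scanner": r.scanner,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_records(path) -> list[SubjectRecord]:
    df = pd.read_csv(
        path, dtype={"subject_id": str, "visit_id": str, "site": str, "scanner": str}
    )
    required = {
        "subject_id", "visit_id", "diagnosis", "age", "sex", "icv", "field_strength",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        for cov in ("age", "icv", "sex", "field_strength"):
            if pd.isna(row[cov]):
                raise ValueError(
                    f"missing covariate {cov!r} for subject {row['subject_id']}"
                )
        records.append(
            SubjectRecord(
                subject_id=row["subject_id"],
                visit_id=row["visit_id"],
                diagnosis=Diagnosis(row["diagnosis"]),
                age=float(row["age"]),
                sex=Sex(row["sex"]),
                icv=float(row["icv"]),
                field_strength=FieldStrength(row["field_strength"]),
                site=str(row.get("site", "site0")),
                scanner=str(row.get("scanner", "scanner0")),
            )
        )
    return records


# -- cohort validation -----------------------------------------------------


@dataclass
class CohortReport:
    """Report-only result of cross-checking metadata against a table."""

    inconsistent_subjects: list[str] = field(default_factory=list)
    orphan_rows: list[tuple[str, str]] = field(default_factory=list)
    missing_rows: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.inconsistent_subjects or self.orphan_rows or self.missing_rows)


def validate_cohort(
    records: Sequence[SubjectRecord], table: FeatureTable | None = None
) -> CohortReport:
    """Flag diagnosis converters and metadata/table mismatches.

    Subjects whose diagnosis differs between visits are listed for
    exclusion; rows of the table without metadata are orphans; metadata
    entries without a table row are missing rows.
    """
    report = CohortReport()
    by_subject: dict[str, set[Diagnosis]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, set()).add(r.diagnosis)
    report.inconsistent_subjects = sorted(
        s for s, dx in by_subject.items() if len(dx) > 1
    )
    if table is not None:
        meta_keys = {(r.subject_id, r.visit_id) for r in records}
        table_keys = set(
            zip(table.ids["subject_id"], table.ids["visit_id"])
        )
        report.orphan_rows = sorted(table_keys - meta_keys)
        report.missing_rows = sorted(meta_keys - table_keys)
    return report


def records_by_key(records: Sequence[SubjectRecord]) -> dict[tuple[str, str], SubjectRecord]:
    return {(r.subject_id, r.visit_id): r for r in records}


def align_records(records: Sequence[SubjectRecord], table: FeatureTable) -> list[SubjectRecord]:
    """Records reordered to match the table's rows; errors on orphans."""
    index = records_by_key(records)
    out = []
    for sid, vid in zip(table.ids["subject_id"], table.ids["visit_id"]):
        key = (str(sid), str(vid))
        if key not in index:
            raise ValueError(f"table row {key} has no metadata record")
        out.append(index[key])
    return out
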