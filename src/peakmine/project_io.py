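"""Reading, writing and grouping of peak tables and sample metadata.

The analysis pipeline consumes two plain-text inputs:

* a *peak table* ("Normalization" file): one row per molecule, a molecule-ID
  column first, optional textual annotation columns (e.g. ``M/Z``, assigned
  metabolite names) and one numeric concentration column per sample.  The
  table is assumed to be aligned and normalized upstream; a concentration of
  exactly ``0`` encodes "not detected".
* a *project info* file: experiment descriptors (id, description, analytical
  platform, MS mode, time unit) followed by a per-sample feature block
  (group, time and arbitrary extra features such as age or gender).

Both files are RFC-4180-style CSV or TSV with a mandatory header row.  The
project-info dialect used here is a two-section CSV: ``key,value`` descriptor
lines, then a sample block introduced by a header line whose first cell is
``sample_id``.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PeakTable",
    "SampleMetadata",
    "Project",
    "read_peak_table",
    "write_peak_table",
    "read_project_info",
    "write_project_info",
    "define_groups",
]


class PeakTableError(ValueError):
    """Raised for malformed peak-table or project-info input."""


# headers that are per-molecule metadata in MS peak tables even when fully
# numeric; auto-selection never treats them as concentration columns
_ANNOTATION_HEADERS = frozenset(
    {"m/z", "mz", "m/z value", "mass", "rt", "retention time", "retention_time"}
)


def _is_number(text: str) -> bool:
    try:
        v = float(text)
    except (TypeError, ValueError):
        return False
    return math.isfinite(v)


@dataclass
class PeakTable:
    """A molecules x samples matrix of non-negative concentrations.

    Parameters
    ----------
    molecule_ids
        Ordered unique molecule labels (row labels).
    sample_ids
        Ordered unique sample labels (column labels).
    values
        Dense float matrix of shape ``(len(molecule_ids), len(sample_ids))``.
        All entries finite and >= 0; ``0`` means "not detected".
    annotations
        Per-molecule textual annotations, one dict entry per annotation
        column, each mapping molecule id -> text.
    """

    molecule_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    annotations: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.molecule_ids = [str(m) for m in self.molecule_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.molecule_ids), len(self.sample_ids)):
            raise PeakTableError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.molecule_ids)}, {len(self.sample_ids)})"
            )
        for name, seq in (("molecule", self.molecule_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(seq)
            if dupes:
                raise PeakTableError(f"duplicate {name} ids: {sorted(dupes)}")
        if not np.all(np.isfinite(self.values)):
            raise PeakTableError("non-finite concentration values")
        if np.any(self.values < 0):
            raise PeakTableError("negative concentration values")

    # -- convenience accessors -------------------------------------------

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def molecule_index(self, molecule: str) -> int:
        try:
            return self.molecule_ids.index(molecule)
        except ValueError:
            raise KeyError(f"unknown molecule {molecule!r}") from None

    def profile(self, molecule: str) -> np.ndarray:
        """Concentration vector of one molecule across all samples."""
        return self.values[self.molecule_index(molecule)]

    def annotation(self, molecule: str, key: str, default: str = "") -> str:
        return self.annotations.get(key, {}).get(molecule, default)

    def subset_molecules(self, keep: Sequence[str]) -> "PeakTable":
        keep_set = set(keep)
        idx = [i for i, m in enumerate(self.molecule_ids) if m in keep_set]
        mols = [self.molecule_ids[i] for i in idx]
        ann = {
            k: {m: v[m] for m in mols if m in v} for k, v in self.annotations.items()
        }
        return PeakTable(mols, list(self.sample_ids), self.values[idx].copy(), ann)

    def to_frame(self) -> pd.DataFrame:
        """Concentration matrix as a DataFrame (molecules x samples)."""
        return pd.DataFrame(self.values, index=self.molecule_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakTable):
            return NotImplemented
        return (
            self.molecule_ids == other.molecule_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
            and self.annotations == other.annotations
        )


@dataclass
class SampleMetadata:
    """Per-sample feature map: group labels, numeric times, extra features."""

    sample_ids: list[str]
    features: pd.DataFrame  # indexed by sample id, one column per feature
    time_unit: str = ""

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if list(self.features.index) != self.sample_ids:
            self.features = self.features.reindex(self.sample_ids)
        if "time" in self.features.columns:
            try:
                self.features["time"] = self.features["time"].astype(float)
            except (TypeError, ValueError) as exc:
                raise PeakTableError(f"unparseable time value: {exc}") from None

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def feature(self, sample: str, name: str):
        return self.features.at[sample, name]

    def time_of(self, sample: str) -> float:
        return float(self.features.at[sample, "time"])

    def align_to(self, table: PeakTable) -> "SampleMetadata":
        """Restrict/extend metadata to a table's samples.

        Samples present in the table but missing from the metadata get empty
        features (with a warning); orphan metadata records are dropped (with
        a warning).
        """
        missing = [s for s in table.sample_ids if s not in self.features.index]
        orphans = [s for s in self.sample_ids if s not in table.sample_ids]
        if missing:
            logger.warning("samples without metadata, assigned empty features: %s", missing)
        if orphans:
            logger.warning("orphan metadata records not in peak table: %s", orphans)
        features = self.features.reindex(table.sample_ids)
        return SampleMetadata(list(table.sample_ids), features, self.time_unit)


@dataclass
class Project:
    """A container of experiments, each a (PeakTable, SampleMetadata) pair."""

    descriptors: dict[str, str] = field(default_factory=dict)
    experiments: dict[str, tuple[PeakTable, SampleMetadata]] = field(default_factory=dict)
    products: dict[str, object] = field(default_factory=dict)

    def add_experiment(self, experiment_id: str, table: PeakTable, metadata: SampleMetadata) -> None:
        if experiment_id in self.experiments:
            raise PeakTableError(f"duplicate experiment id {experiment_id!r}")
        self.experiments[experiment_id] = (table, metadata.align_to(table))


def _duplicates(seq: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for s in seq:
        if s in seen:
            dup.add(s)
        seen.add(s)
    return dup


def _sniff_delimiter(header_line: str) -> str:
    # tabs vs commas in the header; ties resolve to comma
    return "\t" if header_line.count("\t") > header_line.count(",") else ","


def _resolve_delimiter(path: Path, delimiter: str) -> str:
    if delimiter in (",", "\t"):
        return delimiter
    if delimiter == "comma":
        return ","
    if delimiter == "tab":
        return "\t"
    if delimiter == "auto":
        with open(path, "r", newline="") as fh:
            header = fh.readline()
        if not header.strip():
            raise PeakTableError(f"empty file: {path}")
        return _sniff_delimiter(header)
    raise PeakTableError(f"unknown delimiter spec {delimiter!r}")


def read_peak_table(
    path: str | Path,
    delimiter: str = "auto",
    value_columns: Sequence[str] | None = None,
) -> PeakTable:
    """Read a comma- or tab-delimited peak table.

    The first column holds molecule IDs.  When ``value_columns`` is omitted,
    exactly those columns whose every cell parses as a finite number are
    selected as concentration columns; all other columns become textual
    annotations.  When ``value_columns`` is given, each named column must
    exist and be fully numeric (a non-numeric cell is a hard error naming
    its row and column).

    Raises
    ------
    PeakTableError
        On an empty file, duplicate molecule IDs, a missing requested
        column, or a non-numeric cell in a requested value column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _resolve_delimiter(path, delimiter)
    with open(path, "r", newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if not rows:
        raise PeakTableError(f"empty file: {path}")
    header = [c.strip() for c in rows[0]]
    body = rows[1:]
    if not body:
        raise PeakTableError(f"no data rows in {path}")
    width = len(header)
    for i, r in enumerate(body, start=2):
        if len(r) != width:
            raise PeakTableError(f"row {i} has {len(r)} fields, header has {width}")

    id_col = header[0]
    molecule_ids = [r[0].strip() for r in body]
    dupes = _duplicates(molecule_ids)
    if dupes:
        raise PeakTableError(f"duplicate molecule ids: {sorted(dupes)}")

    columns: dict[str, list[str]] = {
        name: [r[j].strip() for r in body] for j, name in enumerate(header)
    }

    if value_columns is not None:
        for name in value_columns:
            if name not in columns:
                raise PeakTableError(f"requested value column {name!r} not in header")
        selected = list(value_columns)
        for name in selected:
            for i, cell in enumerate(columns[name], start=2):
                if not _is_number(cell):
                    raise PeakTableError(
                        f"non-numeric cell {cell!r} at row {i}, column {name!r}"
                    )
    else:
        # auto-selection: a column qualifies iff every cell is a finite
        # number; numeric is necessary but not sufficient — conventional
        # per-molecule MS annotation headers (m/z, retention time) are
        # metadata even though they parse as numbers
        selected = [
            name
            for name in header[1:]
            if name.lower() not in _ANNOTATION_HEADERS
            and all(_is_number(cell) for cell in columns[name])
        ]

    annotation_cols = [c for c in header[1:] if c not in selected and c != id_col]
    values = np.array([[float(v) for v in columns[name]] for name in selected]).T
    if values.size == 0:
        values = values.reshape(len(molecule_ids), 0)
    annotations = {
        name: dict(zip(molecule_ids, columns[name])) for name in annotation_cols
    }
    return PeakTable(molecule_ids, selected, values, annotations)


def write_peak_table(
    table: PeakTable, path: str | Path, delimiter: str = "comma"
) -> Path:
    """Write a peak table so that a read round-trips it exactly.

    Values are serialized with ``repr`` (17 significant digits), which
    float64 round-trips losslessly.
    """
    path = Path(path)
    sep = {"comma": ",", "tab": "\t"}.get(delimiter, delimiter)
    if sep not in (",", "\t"):
        raise PeakTableError(f"unknown delimiter spec {delimiter!r}")
    ann_names = list(table.annotations)
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=sep, lineterminator="\n")
    writer.writerow(["molecule_id", *ann_names, *table.sample_ids])
    for i, mol in enumerate(table.molecule_ids):
        ann = [table.annotations[a].get(mol, "") for a in ann_names]
        writer.writerow([mol, *ann, *[repr(float(v)) for v in table.values[i]]])
    path.write_text(buf.getvalue())
    return path


def read_project_info(path: str | Path) -> tuple[SampleMetadata, dict[str, str]]:
    """Read the two-section project-info CSV.

    The first section is ``key,value`` experiment-descriptor lines (id,
    description, platform, MS mode, ``time_unit``...).  The second section
    starts at the header line whose first cell is ``sample_id`` and lists
    one row per sample with its feature values.  ``time`` values are parsed
    as numbers in the declared time unit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", newline="") as fh:
        rows = [r for r in csv.reader(fh) if any(c.strip() for c in r)]
    if not rows:
        raise PeakTableError(f"empty file: {path}")
    descriptors: dict[str, str] = {}
    sample_header: list[str] | None = None
    sample_rows: list[list[str]] = []
    for r in rows:
        first = r[0].strip()
        if sample_header is None:
            if first == "sample_id":
                sample_header = [c.strip() for c in r]
            else:
                descriptors[first] = r[1].strip() if len(r) > 1 else ""
        else:
            sample_rows.append([c.strip() for c in r])
    if sample_header is None or not sample_rows:
        raise PeakTableError(f"no sample block (header starting 'sample_id') in {path}")
    sample_ids = [r[0] for r in sample_rows]
    data = {
        name: [r[j] if j < len(r) else "" for r in sample_rows]
        for j, name in enumerate(sample_header)
        if j > 0
    }
    features = pd.DataFrame(data, index=sample_ids)
    meta = SampleMetadata(sample_ids, features, descriptors.get("time_unit", ""))
    return meta, descriptors


def write_project_info(
    metadata: SampleMetadata, descriptors: Mapping[str, str], path: str | Path
) -> Path:
    path = Path(path)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    desc = dict(descriptors)
    if metadata.time_unit and "time_unit" not in desc:
        desc["time_unit"] = metadata.time_unit
    for k, v in desc.items():
        writer.writerow([k, v])
    writer.writerow(["sample_id", *metadata.feature_names])
    for s in metadata.sample_ids:
        row = [s]
        for name in metadata.feature_names:
            v = metadata.features.at[s, name]
            if name == "time":
                v = _format_number(float(v))
            row.append("" if v is None or (isinstance(v, float) and math.isnan(v)) else str(v))
        writer.writerow(row)
    path.write_text(buf.getvalue())
    return path


def _format_number(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(v)


def group_label(values: Sequence) -> str:
    """Join feature values into a deterministic group label."""
    parts = []
    for v in values:
        if isinstance(v, float):
            parts.append(_format_number(v))
        else:
            parts.append(str(v))
    return "_".join(parts) if parts else "all"


def define_groups(
    metadata: SampleMetadata, features: Sequence[str]
) -> dict[str, list[str]]:
    """Partition samples into groups by combinations of feature values.

    One group per observed combination; the label is the underscore-joined
    feature values (``"all"`` for the empty feature list).  Groups are
    ordered by first appearance in sample order.  Every sample belongs to
    exactly one group; unobserved combinations are absent.
    """
    for f in features:
        if f not in metadata.feature_names:
            raise KeyError(f"unknown feature {f!r}")
    groups: dict[str, list[str]] = {}
    for s in metadata.sample_ids:
        label = group_label([metadata.features.at[s, f] for f in features])
        groups.setdefault(label, []).append(s)
    return groups
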