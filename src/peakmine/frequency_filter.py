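"""Detection-frequency filtering and molecule/correlation selection.

Aligned peak tables typically contain many spurious low-frequency peaks
(noise).  The two-level detection-frequency filter removes them:

1. *cross-board*: a molecule is retained iff at least one sample group
   reaches the detection-frequency threshold (frequency = fraction of the
   group's samples with a nonzero concentration);
2. *group-based*: within each retained molecule, every group whose
   frequency falls below the threshold has its concentrations set to zero.

Cross-board runs first, so a dropped molecule is never partially zeroed.
"Detected" means a strictly positive value; the threshold comparison is
``>=`` at both levels.  The input table is never mutated.
"""

from __future__ import annotations

import fnmatch
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .project_io import PeakTable, SampleMetadata, define_groups

__all__ = [
    "FrequencyFilterSpec",
    "FilterReport",
    "detection_frequency",
    "apply_frequency_filter",
    "select_molecules",
    "filter_correlations",
    "RangeFilter",
]


@dataclass
class FrequencyFilterSpec:
    """Parameters of the two-level detection-frequency filter."""

    threshold: float = 0.5
    grouping_features: tuple[str, ...] = ("group",)
    apply_cross_board: bool = True
    apply_group_based: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")
        self.grouping_features = tuple(self.grouping_features)


@dataclass
class FilterReport:
    """Outcome of a filter run: who survived, who was zeroed, and why."""

    molecules_retained: list[str]
    molecules_dropped: list[str]
    zeroed_cells: list[tuple[str, str]]  # (molecule, group label)
    frequencies: dict[str, dict[str, float]]  # molecule -> group -> frequency

    def to_tsv(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        buf.write("molecule\tgroup\tfrequency\taction\n")
        zeroed = set(self.zeroed_cells)
        dropped = set(self.molecules_dropped)
        for mol, per_group in self.frequencies.items():
            for grp, freq in per_group.items():
                if mol in dropped:
                    action = "dropped"
                elif (mol, grp) in zeroed:
                    action = "zeroed"
                else:
                    action = "retained"
                buf.write(f"{mol}\t{grp}\t{freq:.6g}\t{action}\n")
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text


def detection_frequency(
    table: PeakTable, molecule: str, sample_subset: Sequence[str]
) -> float:
    """Fraction of the subset's samples in which the molecule is detected."""
    if not sample_subset:
        raise ValueError("empty sample subset")
    row = table.profile(molecule)
    idx = [table.sample_ids.index(s) for s in sample_subset]
    return float(np.count_nonzero(row[idx] > 0)) / len(idx)


def apply_frequency_filter(
    table: PeakTable, metadata: SampleMetadata, spec: FrequencyFilterSpec
) -> tuple[PeakTable, FilterReport]:
    """Apply the cross-board then group-based detection-frequency filter.

    Returns a new table (survivor molecules in input order, samples
    untouched) and a :class:`FilterReport`.  With ``threshold == 0`` the
    filter is the identity.
    """
    groups = define_groups(metadata, list(spec.grouping_features))
    col_idx = {
        label: [table.sample_ids.index(s) for s in samples]
        for label, samples in groups.items()
    }

    frequencies: dict[str, dict[str, float]] = {}
    for i, mol in enumerate(table.molecule_ids):
        row = table.values[i]
        frequencies[mol] = {
            label: float(np.count_nonzero(row[idx] > 0)) / len(idx)
            for label, idx in col_idx.items()
        }

    retained: list[str] = []
    dropped: list[str] = []
    for mol in table.molecule_ids:
        best = max(frequencies[mol].values())
        if (not spec.apply_cross_board) or best >= spec.threshold:
            retained.append(mol)
        else:
            dropped.append(mol)

    keep_idx = [table.molecule_ids.index(m) for m in retained]
    values = table.values[keep_idx].copy()
    zeroed: list[tuple[str, str]] = []
    if spec.apply_group_based:
        for r, mol in enumerate(retained):
            for label, idx in col_idx.items():
                if frequencies[mol][label] < spec.threshold:
                    values[r, idx] = 0.0
                    zeroed.append((mol, label))

    annotations = {
        k: {m: v[m] for m in retained if m in v}
        for k, v in table.annotations.items()
    }
    out = PeakTable(retained, list(table.sample_ids), values, annotations)
    report = FilterReport(retained, dropped, zeroed, frequencies)
    return out, report


def select_molecules(
    table_or_ids: PeakTable | Sequence[str], pattern: str, mode: str = "wildcard"
) -> list[str]:
    """Select molecule IDs by wildcard (``*``/``?``) or regex pattern.

    Matching is a full match against the whole ID; input order is
    preserved.  An invalid regex raises with the parser's message.
    """
    ids = (
        list(table_or_ids.molecule_ids)
        if isinstance(table_or_ids, PeakTable)
        else [str(m) for m in table_or_ids]
    )
    if mode == "wildcard":
        regex = fnmatch.translate(pattern)
    elif mode == "regex":
        regex = pattern
    else:
        raise ValueError(f"unknown mode {mode!r}")
    compiled = re.compile(regex)
    return [m for m in ids if compiled.fullmatch(m)]


@dataclass(frozen=True)
class RangeFilter:
    """Correlation-range visibility filter.

    ``inside`` keeps r in the closed interval [low, high]; ``outside``
    keeps r outside the open interval (low, high), i.e. r <= low or
    r >= high.  The conventional |r| >= c display filter is
    ``RangeFilter(-c, c, "outside")``.
    """

    low: float = -1.0
    high: float = 1.0
    mode: str = "inside"

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"inverted bounds: low={self.low} > high={self.high}")
        if not (-1.0 <= self.low and self.high <= 1.0):
            raise ValueError("bounds must lie in [-1, 1]")
        if self.mode not in ("inside", "outside"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def min_abs(cls, cut: float) -> "RangeFilter":
        return cls(-cut, cut, "outside")

    def keeps(self, r: float) -> bool:
        if self.mode == "inside":
            return self.low <= r <= self.high
        return r <= self.low or r >= self.high


def _edge_r(edge) -> float:
    if isinstance(edge, (int, float, np.floating)):
        return float(edge)
    if hasattr(edge, "r"):
        return float(edge.r)
    if hasattr(edge, "result"):
        return float(edge.result.r)
    return float(edge[-1])  # (a, b, r) tuples


def filter_correlations(
    edges: Iterable, low: float, high: float, mode: str = "inside"
) -> list:
    """Keep edges whose correlation passes the range filter.

    Edges may be bare correlation values, ``(a, b, r)`` tuples, or objects
    with an ``r`` attribute (network edge records).
    """
    rf = RangeFilter(low, high, mode)
    return [e for e in edges if rf.keeps(_edge_r(e))]
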