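"""Synthetic peak tables with planted, recomputable ground truth.

The generator emulates a two-cohort murine time-course metabolomics
design: a control cohort (group ``D``, samples prefixed ``C``) and a test
cohort (group ``DE``, samples prefixed ``T``) sampled at 0, 2 and 4 weeks
with 5, 5, 3 and 5, 7, 5 animals per time point respectively — 30 samples
in total by default.

Planted structure, all recorded in a ground-truth sidecar:

* correlation blocks: members share a latent per-sample factor in log
  space with loading sqrt(target r), so realized pairwise correlations
  approximate the target;
* regulated sets: the test cohort's pre-noise concentrations are scaled
  by an exact fold change (up or down);
* trajectory archetypes: disjoint molecule families share a per-sample
  log-profile, separated from one another by a configurable multiple of
  the within-family spread;
* group-dependent detection dropout: cells of a group are zeroed with a
  per-group probability (after noise, matching the 0 = "not detected"
  sentinel).

Concentrations are log-normal (positive, right-skewed) around per-molecule
base abundances drawn log-uniformly over three decades, mimicking
high-resolution MS peak intensities.  Everything is deterministic per
seed, down to the bytes of the written files.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .project_io import (
    PeakTable,
    SampleMetadata,
    write_peak_table,
    write_project_info,
)

__all__ = ["FixtureSpec", "GroundTruth", "generate_fixture", "write_fixture"]

# default two-cohort time-course design: (group, prefix, {time: n_samples})
DEFAULT_DESIGN = (
    ("D", "C", {0.0: 5, 2.0: 5, 4.0: 3}),
    ("DE", "T", {0.0: 5, 2.0: 7, 4.0: 5}),
)


@dataclass
class FixtureSpec:
    """Parameters of a synthetic peak-table experiment."""

    m: int = 200
    design: tuple = DEFAULT_DESIGN
    time_unit: str = "week"
    correlation_blocks: tuple[tuple[int, float], ...] = ()  # (block size, target r)
    regulated_sets: tuple[tuple[int, float], ...] = ()  # (set size, fold change)
    archetypes: int = 0  # number of trajectory archetype families
    archetype_separation: float = 6.0  # center distance / within-family SD
    dropout: dict = field(default_factory=dict)  # group label -> cell dropout prob
    noise_sigma: float = 0.25  # log-normal multiplicative noise SD (log space)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be positive")
        for size, r in self.correlation_blocks:
            if size < 2 or size > self.m:
                raise ValueError(f"infeasible block size {size} for m={self.m}")
            if abs(r) > 1:
                raise ValueError(f"|target r| must be <= 1, got {r}")
        for size, fc in self.regulated_sets:
            if size < 1 or size > self.m:
                raise ValueError(f"infeasible regulated-set size {size}")
            if fc <= 0:
                raise ValueError(f"fold change must be positive, got {fc}")
        for g, d in self.dropout.items():
            if not 0.0 <= d < 1.0:
                raise ValueError(f"dropout for {g!r} must be in [0, 1), got {d}")
        claimed = sum(s for s, _ in self.correlation_blocks) + sum(
            s for s, _ in self.regulated_sets
        )
        if claimed > self.m:
            raise ValueError(f"planted structures claim {claimed} molecules, only {self.m} available")


@dataclass
class GroundTruth:
    """Planted structure of a generated fixture, verifiable by recomputation."""

    blocks: list[dict]  # {"molecules": [...], "target_r": float}
    up_regulated: dict[str, float]  # molecule -> planted fold change (>1)
    down_regulated: dict[str, float]  # molecule -> planted fold change (<1)
    archetype_of: dict[str, int]  # molecule -> archetype family (1-based)
    dropped_cells: list[tuple[str, str]]  # (molecule, sample)

    def to_tsv(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        buf.write("record\tkey\tvalue\n")
        for i, blk in enumerate(self.blocks, start=1):
            buf.write(f"block\t{i}\t{json.dumps(blk, sort_keys=True)}\n")
        for mol, fc in self.up_regulated.items():
            buf.write(f"up_regulated\t{mol}\t{fc!r}\n")
        for mol, fc in self.down_regulated.items():
            buf.write(f"down_regulated\t{mol}\t{fc!r}\n")
        for mol, a in self.archetype_of.items():
            buf.write(f"archetype\t{mol}\t{a}\n")
        for mol, sample in self.dropped_cells:
            buf.write(f"dropped\t{mol}\t{sample}\n")
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text


def _build_samples(spec: FixtureSpec) -> tuple[list[str], pd.DataFrame]:
    sample_ids: list[str] = []
    groups: list[str] = []
    times: list[float] = []
    for g_label, prefix, per_time in spec.design:
        counter = 1
        for tv in sorted(per_time):
            for _ in range(per_time[tv]):
                sample_ids.append(f"{prefix}{counter:02d}")
                groups.append(g_label)
                times.append(float(tv))
                counter += 1
    features = pd.DataFrame({"group": groups, "time": times}, index=sample_ids)
    return sample_ids, features


def generate_fixture(spec: FixtureSpec) -> tuple[PeakTable, SampleMetadata, GroundTruth]:
    """Generate a peak table + metadata with planted, recorded structure.

    Molecule index ranges are allocated disjointly: correlation blocks
    first, then regulated sets, then archetype families over the
    remainder.  Regulated sets realize their fold change exactly before
    noise; with ``noise_sigma=0`` the realized fold change is exact.
    """
    rng = np.random.default_rng(spec.seed)
    sample_ids, features = _build_samples(spec)
    n = len(sample_ids)
    meta = SampleMetadata(sample_ids, features, spec.time_unit)
    group_of = features["group"].to_dict()
    test_label = spec.design[-1][0]
    test_mask = np.array([group_of[s] == test_label for s in sample_ids])

    molecule_ids = [f"mol{idx + 1:04d}" for idx in range(spec.m)]
    mz = np.sort(rng.uniform(100.0, 1000.0, size=spec.m))
    annotations = {"M/Z": {m: f"{v:.4f}" for m, v in zip(molecule_ids, mz)}}

    base = 10.0 ** rng.uniform(2.0, 5.0, size=spec.m)  # 3 decades of abundance
    log_signal = np.zeros((spec.m, n))

    cursor = 0
    blocks: list[dict] = []
    in_block = np.zeros(spec.m, dtype=bool)
    # block members carry their entire log-variance through the factor
    # structure (no extra independent noise), so the latent correlation is
    # the target exactly; the log amplitude is kept small so that the
    # exponential map preserves it closely on the raw concentration scale
    block_sd = max(0.25, spec.noise_sigma)
    for size, target_r in spec.correlation_blocks:
        members = list(range(cursor, cursor + size))
        factor = rng.standard_normal(n)
        lam = np.sqrt(abs(target_r))
        resid_scale = np.sqrt(1.0 - lam * lam)
        for pos, i in enumerate(members):
            own = rng.standard_normal(n)
            sign = 1.0 if target_r >= 0 or pos == 0 else -1.0
            log_signal[i] += block_sd * (sign * lam * factor + resid_scale * own)
            in_block[i] = True
        blocks.append(
            {"molecules": [molecule_ids[i] for i in members], "target_r": target_r}
        )
        cursor += size

    up: dict[str, float] = {}
    down: dict[str, float] = {}
    for size, fc in spec.regulated_sets:
        members = list(range(cursor, cursor + size))
        for i in members:
            log_signal[i, test_mask] += np.log(fc)
            (up if fc > 1 else down)[molecule_ids[i]] = fc
        cursor += size

    archetype_of: dict[str, int] = {}
    if spec.archetypes > 0:
        rest = list(range(cursor, spec.m))
        if len(rest) < spec.archetypes:
            raise ValueError("not enough molecules left for the requested archetypes")
        # family centers: i.i.d. standard-normal sample profiles; within-family
        # spread chosen so center separation / spread >= the requested ratio
        centers = rng.standard_normal((spec.archetypes, n))
        if spec.archetypes > 1:
            d = np.sqrt(
                ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            )
            min_sep = d[np.triu_indices(spec.archetypes, k=1)].min()
        else:
            min_sep = np.sqrt(2.0 * n)
        # within_sd is the TOTAL within-family log-spread (these molecules
        # skip the independent noise below), so the separation ratio is the
        # realized one, not a pre-noise figure
        within_sd = min_sep / (spec.archetype_separation * np.sqrt(n))
        for j, i in enumerate(rest):
            fam = j % spec.archetypes
            log_signal[i] += centers[fam] + within_sd * rng.standard_normal(n)
            archetype_of[molecule_ids[i]] = fam + 1
            in_block[i] = True

    noise = np.zeros((spec.m, n))
    if spec.noise_sigma > 0:
        free = ~in_block  # block molecules already carry their noise budget
        noise[free] = spec.noise_sigma * rng.standard_normal((int(free.sum()), n))
    values = base[:, None] * np.exp(log_signal + noise)

    dropped: list[tuple[str, str]] = []
    if spec.dropout:
        for j, s in enumerate(sample_ids):
            d = spec.dropout.get(group_of[s], 0.0)
            if d <= 0:
                continue
            mask = rng.random(spec.m) < d
            values[mask, j] = 0.0
            dropped.extend((molecule_ids[i], s) for i in np.nonzero(mask)[0])

    table = PeakTable(molecule_ids, sample_ids, values, annotations)
    truth = GroundTruth(blocks, up, down, archetype_of, dropped)
    return table, meta, truth


def write_fixture(
    fixture: tuple[PeakTable, SampleMetadata, GroundTruth],
    directory: str | Path,
    delimiter: str = "comma",
    descriptors: dict | None = None,
) -> dict[str, Path]:
    """Write the two-file dialect plus a ground-truth sidecar.

    The sidecar (``ground_truth.tsv``) is not part of the analysis input;
    re-generating with the same seed reproduces all three files
    byte-for-byte.
    """
    table, meta, truth = fixture
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    desc = {
        "experiment_id": "synthetic-01",
        "description": "synthetic two-cohort time-course peak table",
        "platform": "synthetic",
        "ms_mode": "none",
    }
    if descriptors:
        desc.update(descriptors)
    paths = {
        "normalization": directory / "Normalization.csv",
        "project_info": directory / "project_info.csv",
        "ground_truth": directory / "ground_truth.tsv",
    }
    write_peak_table(table, paths["normalization"], delimiter)
    write_project_info(meta, desc, paths["project_info"])
    truth.to_tsv(paths["ground_truth"])
    return paths
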