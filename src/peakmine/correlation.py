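"""Pairwise molecular correlation, significance, and network topology.

Three correlation methods are supported on per-molecule concentration
vectors:

* Pearson product-moment: sample covariance / (sd_x * sd_y);
* Spearman rank: Pearson applied to mid-ranks (average ranks for ties);
* Kendall tau-b: (C - D) / sqrt((n0 - T_x)(n0 - T_y)) with
  n0 = n(n-1)/2 and tie corrections T = sum t(t-1)/2 per tied group.

Two-tailed significance uses the t distribution on n-2 degrees of freedom
for Pearson/Spearman (t = r * sqrt((n-2)/(1-r^2))) and the tie-corrected
normal approximation of the tau-b statistic for Kendall.  The one-tailed
probability is half the two-tailed probability, always.

A network stores the full C(m,2) pairwise correlation set; a range filter
only toggles edge *visibility*, never deletes pairs.  Pairs involving a
constant vector (e.g. a molecule fully zeroed by the group-based filter)
carry an explicit "undefined" state and are never visible.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .frequency_filter import RangeFilter
from .project_io import PeakTable

__all__ = [
    "CorrelationResult",
    "Edge",
    "CorrelationNetwork",
    "TopologyStats",
    "correlate_pair",
    "build_network",
    "correlated_neighbors",
    "topology_stats",
    "correlation_scatter",
    "benjamini_hochberg",
]

METHODS = ("pearson", "spearman", "kendall_tau_b")


@dataclass(frozen=True)
class CorrelationResult:
    """One pairwise correlation with its one/two-tailed significance."""

    method: str
    r: float
    n: int
    p_two_tailed: float
    p_one_tailed: float
    undefined: bool = False

    @classmethod
    def make_undefined(cls, method: str, n: int) -> "CorrelationResult":
        return cls(method, float("nan"), n, float("nan"), float("nan"), True)


@dataclass(frozen=True)
class Edge:
    a: str
    b: str
    result: CorrelationResult

    @property
    def r(self) -> float:
        return self.result.r


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    return float((xc * yc).sum() / denom)


def _tie_groups(x: np.ndarray) -> np.ndarray:
    _, counts = np.unique(x, return_counts=True)
    return counts[counts > 1]


def _kendall_tau_b(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tau-b and its two-tailed p (tie-corrected normal approximation)."""
    n = len(x)
    # pairwise sign comparison; O(n^2) but vectorized
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    prod = dx[iu] * dy[iu]
    concordant = int(np.count_nonzero(prod > 0))
    discordant = int(np.count_nonzero(prod < 0))
    s = concordant - discordant

    n0 = n * (n - 1) // 2
    tx = _tie_groups(x)
    ty = _tie_groups(y)
    t_x = int((tx * (tx - 1) // 2).sum())
    t_y = int((ty * (ty - 1) // 2).sum())
    denom = np.sqrt(float(n0 - t_x) * float(n0 - t_y))
    tau = s / denom

    # variance of S with tie corrections (Kendall 1947)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = int((tx * (tx - 1) * (2 * tx + 5)).sum())
    vu = int((ty * (ty - 1) * (2 * ty + 5)).sum())
    v1 = int((tx * (tx - 1)).sum()) * int((ty * (ty - 1)).sum()) / (2.0 * n * (n - 1))
    v2 = (
        int((tx * (tx - 1) * (tx - 2)).sum())
        * int((ty * (ty - 1) * (ty - 2)).sum())
        / (9.0 * n * (n - 1) * (n - 2))
        if n > 2
        else 0.0
    )
    var_s = (v0 - vt - vu) / 18.0 + v1 + v2
    if var_s <= 0:
        return tau, 1.0
    z = s / np.sqrt(var_s)
    p_two = float(2.0 * stats.norm.sf(abs(z)))
    return tau, min(p_two, 1.0)


def _t_pvalue(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlate_pair(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> CorrelationResult:
    """Correlate two equal-length concentration vectors.

    Requires at least 3 observations.  A constant vector makes the
    correlation undefined; an explicitly flagged undefined result is
    returned rather than NaN arising from division.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult.make_undefined(method, n)

    if method == "pearson":
        r = _pearson_r(x, y)
        p_two = _t_pvalue(r, n)
    elif method == "spearman":
        r = _pearson_r(_midranks(x), _midranks(y))
        p_two = _t_pvalue(r, n)
    else:
        r, p_two = _kendall_tau_b(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    return CorrelationResult(method, r, n, p_two, p_two / 2.0)


@dataclass
class CorrelationNetwork:
    """All-pairs correlation store with a visibility range filter.

    ``results`` always holds C(m,2) entries keyed by ``(a, b)`` in input
    molecule order; ``range_filter`` decides which defined pairs are
    visible edges.
    """

    table: PeakTable
    method: str
    results: dict[tuple[str, str], CorrelationResult]
    range_filter: RangeFilter

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.table.molecule_ids)

    def result(self, a: str, b: str) -> CorrelationResult:
        if (a, b) in self.results:
            return self.results[(a, b)]
        if (b, a) in self.results:
            return self.results[(b, a)]
        raise KeyError(f"no pair ({a!r}, {b!r}) in network")

    def is_visible(self, a: str, b: str) -> bool:
        res = self.result(a, b)
        return (not res.undefined) and self.range_filter.keeps(res.r)

    def visible_edges(self) -> list[Edge]:
        return [
            Edge(a, b, res)
            for (a, b), res in self.results.items()
            if not res.undefined and self.range_filter.keeps(res.r)
        ]

    def all_edges(self) -> list[Edge]:
        return [Edge(a, b, res) for (a, b), res in self.results.items()]

    def graph(self) -> nx.Graph:
        """networkx view: all molecules as nodes, visible pairs as edges."""
        g = nx.Graph()
        g.add_nodes_from(self.molecule_ids)
        for e in self.visible_edges():
            g.add_edge(e.a, e.b, r=e.result.r, p_two=e.result.p_two_tailed)
        return g

    def with_filter(self, range_filter: RangeFilter) -> "CorrelationNetwork":
        return CorrelationNetwork(self.table, self.method, self.results, range_filter)

    # -- exports ---------------------------------------------------------

    def edge_list_tsv(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        buf.write("mol_a\tmol_b\tmethod\tr\tp_two\tp_one\tvisible\n")
        for (a, b), res in self.results.items():
            if res.undefined:
                r = p2 = p1 = "undefined"
                vis = "0"
            else:
                r, p2, p1 = repr(res.r), repr(res.p_two_tailed), repr(res.p_one_tailed)
                vis = "1" if self.range_filter.keeps(res.r) else "0"
            buf.write(f"{a}\t{b}\t{self.method}\t{r}\t{p2}\t{p1}\t{vis}\n")
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_graphml(self, path: str | Path) -> Path:
        g = nx.Graph()
        g.add_nodes_from(self.molecule_ids)
        for (a, b), res in self.results.items():
            if res.undefined:
                continue
            g.add_edge(
                a,
                b,
                r=float(res.r),
                p_two=float(res.p_two_tailed),
                visible=bool(self.range_filter.keeps(res.r)),
            )
        nx.write_graphml(g, str(path))
        return Path(path)


def build_network(
    table: PeakTable,
    method: str = "pearson",
    range_filter: RangeFilter | tuple[float, float, str] | None = None,
) -> CorrelationNetwork:
    """Compute all C(m,2) pairwise correlations of a peak table.

    Zeros from non-detection participate in the computation; molecules
    with constant vectors yield undefined (never-visible) pairs.
    """
    if table.n_molecules < 2:
        raise ValueError("need at least 2 molecules")
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples")
    if range_filter is None:
        range_filter = RangeFilter()
    elif isinstance(range_filter, tuple):
        range_filter = RangeFilter(*range_filter)

    mols = table.molecule_ids
    results: dict[tuple[str, str], CorrelationResult] = {}
    if method in ("pearson", "spearman"):
        # vectorized path: correlation matrix in one shot
        data = table.values
        if method == "spearman":
            data = np.apply_along_axis(_midranks, 1, data)
        constant = np.ptp(data, axis=1) == 0
        sd = data.std(axis=1)
        safe = np.where(sd == 0, 1.0, sd)
        z = (data - data.mean(axis=1, keepdims=True)) / safe[:, None]
        rmat = z @ z.T / data.shape[1]
        n = table.n_samples
        for i in range(len(mols)):
            for j in range(i + 1, len(mols)):
                if constant[i] or constant[j]:
                    results[(mols[i], mols[j])] = CorrelationResult.make_undefined(method, n)
                else:
                    r = float(np.clip(rmat[i, j], -1.0, 1.0))
                    p2 = _t_pvalue(r, n)
                    results[(mols[i], mols[j])] = CorrelationResult(method, r, n, p2, p2 / 2.0)
    else:
        for i in range(len(mols)):
            for j in range(i + 1, len(mols)):
                results[(mols[i], mols[j])] = correlate_pair(
                    table.values[i], table.values[j], method
                )
    return CorrelationNetwork(table, method, results, range_filter)


def correlated_neighbors(
    network: CorrelationNetwork, molecule: str, mz_annotation: str = "M/Z"
) -> list[tuple[str, str, float]]:
    """Visible neighbors of a molecule, sorted by |r| descending, ties by id.

    Each entry is ``(neighbor id, M/Z annotation text, r)``.
    """
    if molecule not in network.table.molecule_ids:
        raise KeyError(f"unknown molecule {molecule!r}")
    rows = []
    for e in network.visible_edges():
        if molecule in (e.a, e.b):
            other = e.b if e.a == molecule else e.a
            rows.append((other, network.table.annotation(other, mz_annotation), e.result.r))
    rows.sort(key=lambda t: (-abs(t[2]), t[0]))
    return rows


@dataclass
class TopologyStats:
    """Information-panel statistics of a correlation network."""

    n_correlated_molecules: int  # nodes with at least one visible edge
    n_visible_edges: int
    average_neighbors: float  # 2 |E_visible| / |V|
    degree_histogram: dict[int, int]
    correlation_histogram: dict[tuple[float, float], int]  # all stored pairs
    neighborhood_connectivity: dict[int, float]


def topology_stats(network: CorrelationNetwork, n_bins: int = 20) -> TopologyStats:
    """Degree/correlation distributions and neighborhood connectivity.

    Degree statistics cover visible edges only; the correlation histogram
    covers every stored pair regardless of visibility (undefined pairs
    excluded); neighborhood connectivity maps degree k to the mean, over
    degree-k nodes, of the mean degree of their neighbors.
    """
    g = network.graph()
    degrees = dict(g.degree())
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()

    degree_hist: dict[int, int] = {}
    for d in degrees.values():
        degree_hist[d] = degree_hist.get(d, 0) + 1

    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    rvals = np.array([res.r for res in network.results.values() if not res.undefined])
    counts, _ = np.histogram(rvals, bins=edges) if rvals.size else (np.zeros(n_bins, int), edges)
    corr_hist = {
        (float(edges[i]), float(edges[i + 1])): int(counts[i]) for i in range(n_bins)
    }

    conn_acc: dict[int, list[float]] = {}
    for node, k in degrees.items():
        if k == 0:
            continue
        mean_nb_deg = float(np.mean([degrees[nb] for nb in g.neighbors(node)]))
        conn_acc.setdefault(k, []).append(mean_nb_deg)
    connectivity = {k: float(np.mean(v)) for k, v in sorted(conn_acc.items())}

    return TopologyStats(
        n_correlated_molecules=sum(1 for d in degrees.values() if d > 0),
        n_visible_edges=n_edges,
        average_neighbors=2.0 * n_edges / n_nodes if n_nodes else 0.0,
        degree_histogram=dict(sorted(degree_hist.items())),
        correlation_histogram=corr_hist,
        neighborhood_connectivity=connectivity,
    )


def correlation_scatter(
    table: PeakTable, molecule_a: str, molecule_b: str, method: str = "pearson"
) -> tuple[list[tuple[float, float]], CorrelationResult]:
    """Per-sample (x, y) concentration points for a molecule pair.

    One point per sample in sample order; the attached result equals
    :func:`correlate_pair` on the two profiles.
    """
    xa = table.profile(molecule_a)
    xb = table.profile(molecule_b)
    points = [(float(x), float(y)) for x, y in zip(xa, xb)]
    return points, correlate_pair(xa, xb, method)


def benjamini_hochberg(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default
    everywhere — no multiple-testing correction is applied unless asked)."""
    p = np.asarray(list(pvalues), dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out
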