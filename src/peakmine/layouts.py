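"""Node coordinates and style semantics for network displays.

Six layouts: single circle, multiple circle (up/down/neutral regulation),
random, Kamada-Kawai spring energy, Fruchterman-Reingold force-directed,
and a correlation heatmap.  All layouts are pure functions of
(graph, parameters, seed): repeating a call with the same seed reproduces
coordinates bit-for-bit.

Style semantics: edge color is the signed correlation on a diverging scale
(+1 -> red extreme, -1 -> blue extreme, 0 -> neutral midpoint); node border
encodes regulation (up = green border, down = red border, neutral = none).

The Kamada-Kawai implementation tracks the spring energy

    E = sum_{i<j} k_ij (||p_i - p_j|| - l_ij)^2 / 2

with ideal length l_ij proportional to the graph-theoretic distance, and
guarantees monotone non-increasing energy across iterations via a
step-halving line search on per-node Newton moves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .project_io import PeakTable, SampleMetadata, define_groups
from .correlation import CorrelationNetwork

__all__ = [
    "LayoutResult",
    "RegulationPartition",
    "single_circle_layout",
    "regulation_partition",
    "multiple_circle_layout",
    "kamada_kawai_layout",
    "fruchterman_reingold_layout",
    "random_layout",
    "heatmap_layout",
]


@dataclass
class LayoutResult:
    """2-D coordinates plus node/edge style attributes."""

    coordinates: dict[str, tuple[float, float]]
    node_border: dict[str, str] = field(default_factory=dict)  # up|down|neutral
    edge_color: dict[tuple[str, str], float] = field(default_factory=dict)  # r in [-1,1]
    info: dict = field(default_factory=dict)  # e.g. energy trace for KK

    def positions_array(self, order: Sequence[str] | None = None) -> np.ndarray:
        ids = list(order) if order is not None else list(self.coordinates)
        return np.array([self.coordinates[i] for i in ids], dtype=float)


def _graph_of(network_or_graph) -> nx.Graph:
    if isinstance(network_or_graph, CorrelationNetwork):
        return network_or_graph.graph()
    return network_or_graph


def _style_edges(network_or_graph) -> dict[tuple[str, str], float]:
    if isinstance(network_or_graph, CorrelationNetwork):
        return {(e.a, e.b): e.result.r for e in network_or_graph.visible_edges()}
    g = network_or_graph
    return {(a, b): float(d.get("r", 0.0)) for a, b, d in g.edges(data=True)}


def single_circle_layout(
    nodes: Sequence[str], radius: float = 1.0, center: tuple[float, float] = (0.0, 0.0)
) -> LayoutResult:
    """Place node k of n at angle 2*pi*k/n on a circle, starting at angle 0."""
    nodes = list(nodes)
    if not nodes:
        raise ValueError("need at least one node")
    n = len(nodes)
    cx, cy = center
    coords = {
        node: (
            cx + radius * math.cos(2.0 * math.pi * k / n),
            cy + radius * math.sin(2.0 * math.pi * k / n),
        )
        for k, node in enumerate(nodes)
    }
    return LayoutResult(coords)


@dataclass
class RegulationPartition:
    """Up / down / neutral molecule sets by test-vs-control fold change.

    FC = mean over test samples / mean over control samples; up iff
    FC >= T, down iff FC <= 1/T, neutral otherwise.  A zero control mean
    with detectable test signal yields FC = +inf (up); both means zero is
    neutral.
    """

    up: list[str]
    down: list[str]
    neutral: list[str]
    fold_change: dict[str, float]
    threshold: float

    def label_of(self, molecule: str) -> str:
        if molecule in set(self.up):
            return "up"
        if molecule in set(self.down):
            return "down"
        return "neutral"


def regulation_partition(
    table: PeakTable,
    metadata: SampleMetadata,
    control_group: str,
    test_group: str,
    threshold: float = 2.0,
    grouping_features: Sequence[str] = ("group",),
) -> RegulationPartition:
    """Partition molecules into up/down/neutral by raw-mean fold change."""
    if threshold <= 1.0:
        raise ValueError(f"threshold must exceed 1, got {threshold}")
    groups = define_groups(metadata, list(grouping_features))
    for label in (control_group, test_group):
        if label not in groups:
            raise KeyError(f"unknown group label {label!r}; have {sorted(groups)}")
    ctrl_idx = [table.sample_ids.index(s) for s in groups[control_group]]
    test_idx = [table.sample_ids.index(s) for s in groups[test_group]]

    up: list[str] = []
    down: list[str] = []
    neutral: list[str] = []
    fc_map: dict[str, float] = {}
    for i, mol in enumerate(table.molecule_ids):
        ctrl_mean = float(table.values[i, ctrl_idx].mean())
        test_mean = float(table.values[i, test_idx].mean())
        if ctrl_mean == 0.0 and test_mean == 0.0:
            fc = float("nan")
            neutral.append(mol)
        elif ctrl_mean == 0.0:
            fc = float("inf")
            up.append(mol)
        else:
            fc = test_mean / ctrl_mean
            if fc >= threshold:
                up.append(mol)
            elif fc <= 1.0 / threshold:
                down.append(mol)
            else:
                neutral.append(mol)
        fc_map[mol] = fc
    return RegulationPartition(up, down, neutral, fc_map, threshold)


def multiple_circle_layout(
    partition: RegulationPartition, radius: float = 1.0
) -> LayoutResult:
    """Three horizontally adjacent circles for up, down and neutral sets.

    Each non-empty set is a circle (empty circles are omitted); radii scale
    with sqrt(set size) to limit crowding.  Node borders carry the
    regulation style (up = green, down = red, neutral = none).
    """
    sets = [("up", partition.up), ("down", partition.down), ("neutral", partition.neutral)]
    sets = [(name, nodes) for name, nodes in sets if nodes]
    coords: dict[str, tuple[float, float]] = {}
    borders: dict[str, str] = {}
    x_cursor = 0.0
    for name, nodes in sets:
        r = radius * math.sqrt(len(nodes))
        center = (x_cursor + r, 0.0)
        sub = single_circle_layout(nodes, r, center)
        coords.update(sub.coordinates)
        for node in nodes:
            borders[node] = name
        x_cursor += 2.0 * r + radius  # gap of one base radius between circles
    return LayoutResult(coords, node_border=borders)


# ---------------------------------------------------------------------------
# Kamada-Kawai


def _kk_energy(pos: np.ndarray, lmat: np.ndarray, kmat: np.ndarray) -> float:
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    iu = np.triu_indices(len(pos), k=1)
    return float(0.5 * (kmat[iu] * (dist[iu] - lmat[iu]) ** 2).sum())


def _kk_gradient(pos: np.ndarray, m: int, lmat: np.ndarray, kmat: np.ndarray) -> np.ndarray:
    delta = pos[m] - pos
    dist = np.sqrt((delta**2).sum(axis=1))
    dist[m] = 1.0
    coef = kmat[m] * (1.0 - lmat[m] / dist)
    coef[m] = 0.0
    return (coef[:, None] * delta).sum(axis=0)


def _kk_component(
    nodes: list[str], g: nx.Graph, iterations: int, tolerance: float, rng: np.random.Generator
) -> tuple[dict[str, tuple[float, float]], list[float]]:
    n = len(nodes)
    if n == 1:
        return {nodes[0]: (0.0, 0.0)}, [0.0]
    d = dict(nx.all_pairs_shortest_path_length(g.subgraph(nodes)))
    dmat = np.array([[d[a][b] for b in nodes] for a in nodes], dtype=float)
    lmat = dmat.copy()  # unit ideal edge length
    with np.errstate(divide="ignore"):
        kmat = np.where(dmat > 0, 1.0 / dmat**2, 0.0)

    # deterministic circular start with a small seeded jitter to break symmetry
    angles = 2.0 * np.pi * np.arange(n) / n
    scale = max(1.0, dmat.max() / 2.0)
    pos = scale * np.column_stack([np.cos(angles), np.sin(angles)])
    pos += 0.01 * scale * rng.standard_normal(pos.shape)

    energies = [_kk_energy(pos, lmat, kmat)]
    for _ in range(iterations):
        grads = np.array([_kk_gradient(pos, m, lmat, kmat) for m in range(n)])
        norms = np.sqrt((grads**2).sum(axis=1))
        m = int(norms.argmax())
        if norms[m] < tolerance:
            break
        # 2x2 Newton step for node m (Hessian of E wrt p_m)
        delta = pos[m] - pos
        dist = np.sqrt((delta**2).sum(axis=1))
        dist[m] = 1.0
        dx, dy = delta[:, 0], delta[:, 1]
        k_row, l_row = kmat[m].copy(), lmat[m]
        k_row[m] = 0.0
        d3 = dist**3
        exx = (k_row * (1.0 - l_row * dy**2 / d3)).sum()
        eyy = (k_row * (1.0 - l_row * dx**2 / d3)).sum()
        exy = (k_row * l_row * dx * dy / d3).sum()
        hess = np.array([[exx, exy], [exy, eyy]])
        try:
            step = np.linalg.solve(hess, -grads[m])
        except np.linalg.LinAlgError:
            step = -grads[m]
        # line search: halve until energy does not increase
        e_prev = energies[-1]
        for _ in range(40):
            cand = pos.copy()
            cand[m] = pos[m] + step
            e_new = _kk_energy(cand, lmat, kmat)
            if e_new <= e_prev:
                break
            step = step / 2.0
        else:
            e_new = e_prev
            cand = pos
        pos = cand
        energies.append(e_new)
    coords = {node: (float(x), float(y)) for node, (x, y) in zip(nodes, pos)}
    return coords, energies


def _pack_components(
    layouts: list[dict[str, tuple[float, float]]], pad: float = 1.0
) -> dict[str, tuple[float, float]]:
    """Place independently laid-out components on a grid."""
    if len(layouts) == 1:
        return layouts[0]
    boxes = []
    for lay in layouts:
        arr = np.array(list(lay.values()))
        lo, hi = arr.min(axis=0), arr.max(axis=0)
        boxes.append((lay, lo, hi - lo))
    ncols = int(math.ceil(math.sqrt(len(boxes))))
    cell_w = max(b[2][0] for b in boxes) + pad
    cell_h = max(b[2][1] for b in boxes) + pad
    merged: dict[str, tuple[float, float]] = {}
    for idx, (lay, lo, _) in enumerate(boxes):
        ox = (idx % ncols) * cell_w - lo[0]
        oy = (idx // ncols) * cell_h - lo[1]
        for node, (x, y) in lay.items():
            merged[node] = (x + ox, y + oy)
    return merged


def kamada_kawai_layout(
    network_or_graph,
    iterations: int = 1000,
    tolerance: float = 1e-6,
    seed: int = 0,
) -> LayoutResult:
    """Spring-energy layout with ideal lengths from shortest-path distance.

    Connected components are laid out independently and packed on a grid.
    The per-component energy traces (monotone non-increasing) are returned
    in ``info["energy"]``.
    """
    g = _graph_of(network_or_graph)
    if g.number_of_nodes() == 0:
        return LayoutResult({})
    rng = np.random.default_rng(seed)
    component_layouts = []
    traces = []
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        coords, energies = _kk_component(nodes, g, iterations, tolerance, rng)
        component_layouts.append(coords)
        traces.append(energies)
    coords = _pack_components(component_layouts)
    return LayoutResult(coords, edge_color=_style_edges(network_or_graph), info={"energy": traces})


def fruchterman_reingold_layout(
    network_or_graph, iterations: int = 100, seed: int = 0
) -> LayoutResult:
    """Classic force-directed embedding with linear temperature cooling.

    Attractive force d^2/k along edges, repulsive k^2/d between all node
    pairs, displacement capped by a temperature that cools linearly.
    """
    g = _graph_of(network_or_graph)
    nodes = list(g.nodes())
    n = len(nodes)
    if n == 0:
        return LayoutResult({})
    if n == 1:
        return LayoutResult({nodes[0]: (0.5, 0.5)})
    rng = np.random.default_rng(seed)
    pos = rng.random((n, 2))
    index = {node: i for i, node in enumerate(nodes)}
    edges = np.array([(index[a], index[b]) for a, b in g.edges()], dtype=int)
    k = math.sqrt(1.0 / n)
    t0 = 0.1
    for it in range(iterations):
        t = t0 * (1.0 - it / iterations)
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((delta**2).sum(axis=2))
        np.fill_diagonal(dist, 1e-9)
        disp = ((k * k / dist**2)[:, :, None] * delta).sum(axis=1)
        if len(edges):
            d_e = pos[edges[:, 0]] - pos[edges[:, 1]]
            dist_e = np.sqrt((d_e**2).sum(axis=1))[:, None]
            dist_e[dist_e == 0] = 1e-9
            f_attr = (dist_e / k) * d_e
            np.add.at(disp, edges[:, 0], -f_attr)
            np.add.at(disp, edges[:, 1], f_attr)
        lengths = np.sqrt((disp**2).sum(axis=1))
        lengths[lengths == 0] = 1e-9
        pos += disp / lengths[:, None] * np.minimum(lengths, t)[:, None]
    coords = {node: (float(x), float(y)) for node, (x, y) in zip(nodes, pos)}
    return LayoutResult(coords, edge_color=_style_edges(network_or_graph))


def random_layout(nodes: Sequence[str], seed: int = 0) -> LayoutResult:
    """Uniform coordinates in the unit square, deterministic per seed."""
    nodes = list(nodes)
    rng = np.random.default_rng(seed)
    pts = rng.random((len(nodes), 2))
    return LayoutResult({node: (float(x), float(y)) for node, (x, y) in zip(nodes, pts)})


def heatmap_layout(network: CorrelationNetwork) -> tuple[np.ndarray, list[str]]:
    """m x m matrix of correlation color values plus the molecule ordering.

    Cells hold the signed correlation in [-1, 1]; pairs filtered out of
    visibility, undefined pairs and the diagonal carry NaN as the neutral
    (background) value.  Ordering is the input molecule order (no
    seriation); the matrix is symmetric.
    """
    mols = network.molecule_ids
    m = len(mols)
    mat = np.full((m, m), np.nan)
    idx = {mol: i for i, mol in enumerate(mols)}
    for (a, b), res in network.results.items():
        if res.undefined or not network.range_filter.keeps(res.r):
            continue
        i, j = idx[a], idx[b]
        mat[i, j] = mat[j, i] = res.r
    return mat, list(mols)
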