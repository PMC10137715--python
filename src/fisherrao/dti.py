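"""Tensor-field distances on regular grids (DTI-style application).

A diffusion-tensor field stores one SPD covariance per voxel of a 2D or 3D
grid; together with the voxel's physical position as mean this defines one
normal distribution per voxel.  Fisher-Rao distances between distant voxels
are approximated by shortest paths (Dijkstra) on the neighbor graph whose
edges are weighted by a chosen two-point distance between adjacent voxels'
normals: the Calvo-Oller lower bound (``co``), a discretized curve length
(``curve:co`` / ``curve:m``), or the square root of the Jeffreys divergence
(``sqrt-jeffreys``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .calvo_oller import rho_co
from .closed_forms import jeffreys_upper_bound
from .curves import curve_length
from .gaussian import Gaussian, validate_spd

__all__ = ["TensorGrid", "build_graph", "grid_distance", "distance_map"]

_CONNECTIVITY = {2: (4, 8), 3: (6, 26)}
_METRICS = ("co", "curve:co", "curve:m", "sqrt-jeffreys")


@dataclass(frozen=True)
class TensorGrid:
    """A lattice of normals: per-voxel SPD tensors plus voxel spacing.

    ``covs`` has shape ``(*shape, d, d)``; means default to the voxel's
    physical coordinate ``index * spacing`` unless ``means`` (shape
    ``(*shape, d)``) is given.
    """

    covs: np.ndarray
    spacing: tuple[float, ...]
    means: np.ndarray | None = None

    def __post_init__(self) -> None:
        covs = np.asarray(self.covs, dtype=float)
        ndim = covs.ndim - 2
        if ndim not in (2, 3):
            raise ValueError("covs must have shape (*grid_shape, d, d), 2D or 3D grid")
        d = covs.shape[-1]
        if covs.shape[-2] != d:
            raise ValueError("per-voxel tensors must be square")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != ndim or any(s <= 0 for s in spacing):
            raise ValueError("spacing must give one positive step per grid axis")
        for idx in np.ndindex(covs.shape[:-2]):
            validate_spd(covs[idx], f"cov at voxel {idx}")
        means = self.means
        if means is not None:
            means = np.asarray(means, dtype=float)
            if means.shape != covs.shape[:-2] + (d,):
                raise ValueError("means must have shape (*grid_shape, d)")
        object.__setattr__(self, "covs", covs)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "means", means)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.covs.shape[:-2]

    @property
    def d(self) -> int:
        return self.covs.shape[-1]

    def gaussian(self, voxel: tuple[int, ...]) -> Gaussian:
        if self.means is not None:
            mean = self.means[voxel]
        else:
            # physical coordinate, padded with zeros when tensor dimension
            # exceeds the grid dimension (e.g. 3x3 tensors on a 2D slice)
            mean = np.zeros(self.d)
            coords = np.asarray(voxel, dtype=float) * np.asarray(self.spacing)
            mean[: len(coords)] = coords
        return Gaussian(mean, self.covs[voxel])


def _neighbor_offsets(ndim: int, connectivity: int) -> list[tuple[int, ...]]:
    if connectivity not in _CONNECTIVITY[ndim]:
        raise ValueError(
            f"connectivity {connectivity} invalid for {ndim}D grid; "
            f"choose from {_CONNECTIVITY[ndim]}"
        )
    full = connectivity in (8, 26)
    offs = []
    for off in itertools.product((-1, 0, 1), repeat=ndim):
        if all(o == 0 for o in off):
            continue
        if not full and sum(abs(o) for o in off) != 1:
            continue
        offs.append(off)
    return offs


def build_graph(
    grid: TensorGrid, connectivity: int, metric: str = "co", T: int = 20
) -> nx.Graph:
    """Weighted neighbor graph of a tensor grid.

    Nodes are voxel index tuples; each voxel links to its 4/8 (2D) or 6/26
    (3D) neighborhood with the chosen two-point distance as edge weight
    (each unordered pair computed once).  The graph records the metric tag
    as ``graph.graph["metric"]``.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")
    offsets = _neighbor_offsets(len(grid.shape), connectivity)
    shape = grid.shape
    G = nx.Graph(metric=metric)
    cache: dict[tuple[int, ...], Gaussian] = {}

    def gauss(v: tuple[int, ...]) -> Gaussian:
        if v not in cache:
            cache[v] = grid.gaussian(v)
        return cache[v]

    for v in np.ndindex(shape):
        G.add_node(v)
    for v in np.ndindex(shape):
        for off in offsets:
            w = tuple(a + b for a, b in zip(v, off))
            if any(c < 0 or c >= s for c, s in zip(w, shape)):
                continue
            if G.has_edge(v, w):
                continue
            G.add_edge(v, w, weight=_pair_distance(gauss(v), gauss(w), metric, T))
    return G


def _pair_distance(g1: Gaussian, g2: Gaussian, metric: str, T: int) -> float:
    if metric == "co":
        return rho_co(g1, g2)
    if metric == "curve:co":
        return curve_length("co-projected", g1, g2, T, nodes="full")
    if metric == "curve:m":
        return curve_length("mixture", g1, g2, T, nodes="full")
    if metric == "sqrt-jeffreys":
        return jeffreys_upper_bound(g1, g2)
    raise ValueError(f"unknown metric {metric!r}")


def grid_distance(
    graph: nx.Graph, a: tuple[int, ...], b: tuple[int, ...]
) -> float:
    """Shortest-path (Dijkstra) distance between two voxels on the weighted
    neighbor graph."""
    return float(nx.dijkstra_path_length(graph, tuple(a), tuple(b)))


def distance_map(graph: nx.Graph, source: tuple[int, ...]) -> dict[tuple[int, ...], float]:
    """Single-source Dijkstra distances to every voxel."""
    return {
        k: float(v)
        for k, v in nx.single_source_dijkstra_path_length(graph, tuple(source)).items()
    }
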