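"""Cell meshes and discrete Laplacians.

Three surface discretizations are supported: a rectangular grid (the test and
quantification surface), a sphere ("pure species"), and a fused two-ball
implicit surface, i.e. a metaball ("hybrid").  Point-cloud meshes use a
k-nearest-neighbour graph Laplacian with inverse-distance weights,
symmetrized, with the diagonal set to minus the row sum so that the operator
annihilates constant fields exactly.  Point clouds are rescaled so that the
mean nearest-neighbour spacing is 1, making diffusion coefficients comparable
with the unit-spacing grid; a single calibration constant (estimated once on a
reference sphere, where the Laplace–Beltrami spectrum is known) scales the
graph operator so that grid and point-cloud Laplacians agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "CellMesh",
    "make_grid_mesh",
    "make_sphere_mesh",
    "make_metaball_mesh",
]

DEFAULT_KNN = 6


@dataclass
class CellMesh:
    """A set of cells with a discrete Laplacian.

    ``axis_coordinate`` (in [0, 1]) locates each cell along the blend axis and
    is present only on metaball meshes.  ``grid_shape`` allows grid fields to
    be reshaped into images.
    """

    coordinates: np.ndarray
    laplacian: sp.csr_matrix
    geometry_tag: str
    neighbors: list[np.ndarray] | None = None
    axis_coordinate: np.ndarray | None = None
    grid_shape: tuple[int, int] | None = None

    @property
    def n_cells(self) -> int:
        return self.coordinates.shape[0]

    def apply_laplacian(self, f: np.ndarray) -> np.ndarray:
        return self.laplacian @ f


def make_grid_mesh(width: int, height: int, periodic: bool = False) -> CellMesh:
    """Rectangular grid with the 5-point Laplacian stencil (unit spacing).

    Cells are indexed row-major as ``(row, col) -> row * width + col``; with
    ``periodic`` the domain wraps in both directions, otherwise no-flux
    (Neumann) boundaries arise naturally from the graph construction.
    """
    if width < 8 or height < 8:
        raise ValueError("grid must be at least 8x8 cells")
    n = width * height
    rows_idx, cols_idx, data = [], [], []
    idx = np.arange(n).reshape(height, width)
    neigh: list[list[int]] = [[] for _ in range(n)]

    def link(a: np.ndarray, b: np.ndarray) -> None:
        rows_idx.extend(a.ravel())
        cols_idx.extend(b.ravel())
        data.extend(np.ones(a.size))

    if periodic:
        link(idx, np.roll(idx, 1, axis=1))
        link(idx, np.roll(idx, -1, axis=1))
        link(idx, np.roll(idx, 1, axis=0))
        link(idx, np.roll(idx, -1, axis=0))
    else:
        link(idx[:, 1:], idx[:, :-1])
        link(idx[:, :-1], idx[:, 1:])
        link(idx[1:, :], idx[:-1, :])
        link(idx[:-1, :], idx[1:, :])
    adj = sp.csr_matrix((data, (rows_idx, cols_idx)), shape=(n, n))
    lap = adj - sp.diags(np.asarray(adj.sum(axis=1)).ravel())
    ys, xs = np.divmod(np.arange(n), width)
    coords = np.column_stack([xs.astype(float), ys.astype(float)])
    neighbors = [adj.indices[adj.indptr[i]:adj.indptr[i + 1]] for i in range(n)]
    return CellMesh(coords, lap.tocsr(), "grid", neighbors=neighbors, grid_shape=(height, width))


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _point_cloud_laplacian(coords: np.ndarray, k: int):
    """Inverse-distance kNN Laplacian on a point cloud (before scaling).

    Returns ``(laplacian, neighbors, mean_nn_distance)``.  The operator is
    symmetrized (union of directed kNN edges, averaged weights), so row sums
    are exactly zero by construction of the diagonal.
    """
    tree = cKDTree(coords)
    dist, nbr = tree.query(coords, k=k + 1)
    dist, nbr = dist[:, 1:], nbr[:, 1:]
    n = coords.shape[0]
    rows = np.repeat(np.arange(n), k)
    cols = nbr.ravel()
    w = 1.0 / dist.ravel()
    W = sp.csr_matrix((w, (rows, cols)), shape=(n, n))
    W = (W + W.T) / 2.0
    lap = W - sp.diags(np.asarray(W.sum(axis=1)).ravel())
    neighbors = [nbr[i] for i in range(n)]
    return lap.tocsr(), neighbors, float(dist[:, 0].mean())


@lru_cache(maxsize=4)
def _laplacian_scale(k: int = DEFAULT_KNN, n_ref: int = 2000) -> float:
    """Calibration constant for point-cloud Laplacians.

    On a reference Fibonacci sphere (rescaled to unit mean spacing, radius
    rho) the coordinate function z is a Laplace–Beltrami eigenfunction with
    eigenvalue -2/rho^2.  The least-squares ratio between the graph operator
    applied to z and the analytic value gives the scale factor; it depends
    only on the local lattice statistics (k and unit spacing) and therefore
    transfers to any quasi-uniform point cloud built the same way.
    """
    pts = _fibonacci_sphere(n_ref)
    lap, _, h = _point_cloud_laplacian(pts, k)
    pts = pts / h  # unit mean nn spacing; operator weights rescale by h
    lap = lap * h
    rho = 1.0 / h
    z = pts[:, 2]
    rayleigh = -float((lap @ z) @ z) / float(z @ z)
    return (2.0 / rho**2) / rayleigh


def make_sphere_mesh(n_cells: int, k: int = DEFAULT_KNN) -> CellMesh:
    """Quasi-uniform cells on a sphere (Fibonacci lattice, kNN Laplacian).

    The sphere is scaled so neighbouring cells are ~1 unit apart, hence its
    radius grows like ``sqrt(n_cells)`` and diffusion lengths match grid runs.
    """
    if n_cells < 100:
        raise ValueError("need at least 100 cells for a stable kNN Laplacian")
    pts = _fibonacci_sphere(n_cells)
    lap, neighbors, h = _point_cloud_laplacian(pts, k)
    coords = pts / h
    lap = lap * (h * _laplacian_scale(k))
    return CellMesh(coords, lap, "sphere", neighbors=neighbors)


def _metaball_field(x: np.ndarray, c1: np.ndarray, c2: np.ndarray, r: float):
    d1 = np.maximum(np.linalg.norm(x - c1, axis=-1), 1e-9)
    d2 = np.maximum(np.linalg.norm(x - c2, axis=-1), 1e-9)
    return (r / d1) ** 2 + (r / d2) ** 2


def _metaball_grad(x: np.ndarray, c1: np.ndarray, c2: np.ndarray, r: float):
    g = np.zeros_like(x)
    for c in (c1, c2):
        diff = x - c
        d2 = np.maximum((diff**2).sum(axis=-1, keepdims=True), 1e-18)
        g += -2.0 * r**2 * diff / d2**2
    return g


def _project_to_isosurface(x, c1, c2, r, iters: int = 40):
    for _ in range(iters):
        f = _metaball_field(x, c1, c2, r) - 1.0
        g = _metaball_grad(x, c1, c2, r)
        gn = (g**2).sum(axis=-1, keepdims=True)
        x = x - (f[:, None] * g) / np.maximum(gn, 1e-18)
    return x


def make_metaball_mesh(
    n_cells: int,
    separation: float = 2.4,
    radius: float = 1.0,
    k: int = DEFAULT_KNN,
    relax_iters: int = 30,
    seed: int = 0,
) -> CellMesh:
    """Cells on the fused surface of two overlapping balls.

    The implicit field is ``(r/d1)^2 + (r/d2)^2 = 1``; the two balls fuse into
    a single surface for ``separation < 2*sqrt(2)*radius``.  Points are seeded
    on the two spheres, projected onto the isosurface, and relaxed by local
    repulsion to even out spacing.  ``axis_coordinate`` in [0, 1] is each
    cell's normalized projection onto the line joining the two ball centres
    (the blend axis), with the two extreme cells at exactly 0 and 1.
    """
    if n_cells < 100:
        raise ValueError("need at least 100 cells for a stable kNN Laplacian")
    c1 = np.array([-separation / 2.0, 0.0, 0.0])
    c2 = -c1
    rng = np.random.default_rng(seed)
    half = n_cells // 2
    pts = np.vstack(
        [
            c1 + radius * _fibonacci_sphere(half),
            c2 + radius * _fibonacci_sphere(n_cells - half),
        ]
    )
    pts += rng.normal(scale=0.01 * radius, size=pts.shape)
    pts = _project_to_isosurface(pts, c1, c2, radius)
    # local repulsion to even out the seam region, reprojecting each step
    for _ in range(relax_iters):
        tree = cKDTree(pts)
        dist, nbr = tree.query(pts, k=4)
        dist, nbr = dist[:, 1:], nbr[:, 1:]
        target = np.median(dist)
        push = np.zeros_like(pts)
        for j in range(nbr.shape[1]):
            diff = pts - pts[nbr[:, j]]
            d = np.maximum(dist[:, j], 1e-9)[:, None]
            push += diff / d * np.maximum(target - dist[:, j], 0.0)[:, None]
        pts = _project_to_isosurface(pts + 0.5 * push, c1, c2, radius, iters=5)
    lap, neighbors, h = _point_cloud_laplacian(pts, k)
    adj = sp.csr_matrix(
        (
            np.ones(sum(len(a) for a in neighbors)),
            (
                np.repeat(np.arange(len(neighbors)), [len(a) for a in neighbors]),
                np.concatenate(neighbors),
            ),
        ),
        shape=(len(neighbors),) * 2,
    )
    n_comp, _ = connected_components(adj + adj.T, directed=False)
    if n_comp != 1:
        raise ValueError(
            f"metaball surface is disconnected ({n_comp} components); reduce separation"
        )
    coords = pts / h
    lap = lap * (h * _laplacian_scale(k))
    axis = coords @ (np.array([1.0, 0.0, 0.0]))
    axis = (axis - axis.min()) / (axis.max() - axis.min())
    return CellMesh(coords, lap, "metaball", neighbors=neighbors, axis_coordinate=axis)
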