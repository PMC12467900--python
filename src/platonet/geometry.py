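"""Hollow-ellipsoid shell geometry and its harmonic bond topology.

The platelet is a single-layer triangulated shell: quasi-uniform points on
the unit sphere (Fibonacci lattice) are mapped affinely onto the ellipsoid,
triangulated by their convex hull (equivalent to a spherical Delaunay
triangulation for such point sets), and every triangulation edge becomes a
harmonic bond whose rest length is the initial edge length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull

__all__ = ["PlateletGeometry", "build_ellipsoid_shell", "curvature_proxy"]


class GeometryError(ValueError):
    pass


@dataclass
class PlateletGeometry:
    """Shell vertices, semi-axes, and bond topology.

    ``bonds`` is an (E, 2) integer array with i < j per row, and
    ``rest_lengths`` the matching (E,) initial edge lengths.
    """

    positions: np.ndarray          # (V, 3) float
    semi_axes: tuple[float, float, float]
    bonds: np.ndarray              # (E, 2) int, i < j, unique rows
    rest_lengths: np.ndarray       # (E,)
    n_faces: int = 0
    seed: int = 0
    neighbors: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.bonds = np.asarray(self.bonds, dtype=np.int64)
        self.rest_lengths = np.asarray(self.rest_lengths, dtype=float)
        if np.any(self.bonds[:, 0] >= self.bonds[:, 1]):
            raise GeometryError("bonds must satisfy i < j")
        if len(np.unique(self.bonds, axis=0)) != len(self.bonds):
            raise GeometryError("duplicate bonds")
        if not self.neighbors:
            self.neighbors = self._build_neighbors()

    def _build_neighbors(self) -> list[np.ndarray]:
        nbr: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for i, j in self.bonds:
            nbr[i].append(j)
            nbr[j].append(i)
        return [np.array(sorted(n), dtype=np.int64) for n in nbr]

    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def major_diameter(self) -> float:
        return 2.0 * max(self.semi_axes)

    def degree(self) -> np.ndarray:
        return np.array([len(n) for n in self.neighbors])

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_bonds + self.n_faces

    def is_connected(self) -> bool:
        e = self.bonds
        data = np.ones(len(e))
        adj = coo_matrix(
            (data, (e[:, 0], e[:, 1])), shape=(self.n_vertices, self.n_vertices)
        )
        n_comp, _ = connected_components(adj, directed=False)
        return n_comp == 1


def _fibonacci_sphere(n: int, phase: float) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-angle lattice)."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + math.sqrt(5.0)) / 2.0
    theta = 2.0 * math.pi * ((i / golden + phase) % 1.0)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def build_ellipsoid_shell(
    semi_axes: tuple[float, float, float],
    n_target: int,
    seed: int = 0,
) -> PlateletGeometry:
    """Build a triangulated hollow-ellipsoid shell of ~``n_target`` vertices.

    The seed only shifts the phase of the Fibonacci lattice; the build is
    bit-for-bit reproducible for a fixed seed.
    """
    a, b, c = (float(s) for s in semi_axes)
    if min(a, b, c) <= 0:
        raise GeometryError("semi-axes must be positive")
    if n_target < 12:
        raise GeometryError(f"n_target={n_target} too small to triangulate a shell")

    phase = (np.random.SeedSequence(seed).generate_state(1)[0] % 10_000) / 10_000.0
    unit = _fibonacci_sphere(int(n_target), phase)
    # Affine map to the ellipsoid; the convex hull of the mapped points is
    # combinatorially a sphere triangulation (the map preserves convexity).
    pos = unit * np.array([a, b, c])
    hull = ConvexHull(pos)
    faces = hull.simplices
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [0, 2]]])
    edges = np.sort(edges, axis=1)
    edges = np.unique(edges, axis=0)
    rest = np.linalg.norm(pos[edges[:, 0]] - pos[edges[:, 1]], axis=1)
    geom = PlateletGeometry(
        positions=pos,
        semi_axes=(a, b, c),
        bonds=edges,
        rest_lengths=rest,
        n_faces=len(faces),
        seed=int(seed),
    )
    if not geom.is_connected():
        raise GeometryError("shell triangulation is not connected")
    return geom


def curvature_proxy(geom: PlateletGeometry, positions: np.ndarray | None = None) -> np.ndarray:
    """Per-vertex mean Euclidean distance to bonded neighbours.

    Used as the local-curvature proxy when binning surrogate errors by
    geometry: on a deformed shell, tightly bent or stretched regions shift
    this statistic away from its rest-mesh value.
    """
    pos = geom.positions if positions is None else np.asarray(positions, dtype=float)
    if pos.shape != geom.positions.shape:
        raise GeometryError(
            f"positions shape {pos.shape} does not match geometry "
            f"{geom.positions.shape}"
        )
    out = np.empty(geom.n_vertices)
    for v, nbr in enumerate(geom.neighbors):
        if len(nbr) == 0:
            raise GeometryError(f"vertex {v} has no bonds")
        out[v] = np.mean(np.linalg.norm(pos[nbr] - pos[v], axis=1))
    return out
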