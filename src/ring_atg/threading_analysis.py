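"""Inter-ring threading via minimal disk-like surfaces, and linking numbers.

Threading is a physical (non-permanent) topological constraint distinct from
concatenation: ring j threads ring i when a bond of j pierces the minimal
disk-like surface spanned on i's contour, while the pair's Gauss linking
number remains zero.  The surface is built as a centroid fan over the
(polygonal) contour, refined by 1-to-4 triangle subdivision, and relaxed by
monotone area-gradient descent with the boundary held fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _engine
from .core import Frame, Topology


@dataclass
class SurfaceMesh:
    """Triangulated disk spanning one ring contour.

    ``vertices[:n_boundary]`` are boundary vertices fixed on the (polygonal)
    ring contour; the rest are free interior vertices.
    """

    vertices: np.ndarray  # (V, 3)
    triangles: np.ndarray  # (T, 3) int
    boundary_mask: np.ndarray  # (V,) bool
    area: float
    converged: bool = True

    def euler_characteristic(self) -> int:
        v = self.vertices.shape[0]
        f = self.triangles.shape[0]
        edges = set()
        for a, b, c in self.triangles:
            for e in ((a, b), (b, c), (c, a)):
                edges.add((min(e), max(e)))
        return v - len(edges) + f


def triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    a = vertices[triangles[:, 0]]
    b = vertices[triangles[:, 1]]
    c = vertices[triangles[:, 2]]
    n = np.cross(b - a, c - a)
    return 0.5 * np.linalg.norm(n, axis=1)


def _area_gradient(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Gradient of total triangle area with respect to every vertex."""
    a = vertices[triangles[:, 0]]
    b = vertices[triangles[:, 1]]
    c = vertices[triangles[:, 2]]
    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n, axis=1)
    ok = nn > 1e-14
    nhat = np.zeros_like(n)
    nhat[ok] = n[ok] / nn[ok, None]
    grad = np.zeros_like(vertices)
    # dA/da = ((b - c) x nhat) / 2, cyclic
    np.add.at(grad, triangles[:, 0], 0.5 * np.cross(b - c, nhat))
    np.add.at(grad, triangles[:, 1], 0.5 * np.cross(c - a, nhat))
    np.add.at(grad, triangles[:, 2], 0.5 * np.cross(a - b, nhat))
    return grad


def _refine(vertices: np.ndarray, triangles: np.ndarray,
            boundary_mask: np.ndarray):
    """1-to-4 subdivision; midpoints of boundary edges stay on the contour."""
    edge_mid: dict[tuple[int, int], int] = {}
    verts = [v for v in vertices]
    bnd = list(boundary_mask)

    def midpoint(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        if key not in edge_mid:
            verts.append(0.5 * (vertices[i] + vertices[j]))
            # midpoint of a boundary edge lies on the polygonal contour
            bnd.append(bool(boundary_mask[i] and boundary_mask[j]))
            edge_mid[key] = len(verts) - 1
        return edge_mid[key]

    new_tris = []
    for a, b, c in triangles:
        ab = midpoint(a, b)
        bc = midpoint(b, c)
        ca = midpoint(c, a)
        new_tris.extend([(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)])
    return (np.array(verts), np.array(new_tris, dtype=np.int64),
            np.array(bnd, dtype=bool))


def build_minimal_surface(ring: np.ndarray, *, n_refine: int = 2,
                          tol: float = 1e-5, max_sweeps: int = 2000,
                          ) -> SurfaceMesh:
    """Near-minimal disk spanning a closed polygonal ring contour.

    Starts from a fan triangulation rooted at the contour centroid, applies
    ``n_refine`` rounds of 1-to-4 subdivision, and relaxes interior vertices
    by backtracking gradient descent on the total area (monotone decrease by
    construction) until the relative area change per sweep drops below
    ``tol``.  Non-convergence yields a best-effort mesh flagged
    ``converged=False`` with a warning.
    """
    ring = np.asarray(ring, dtype=float)
    nb = ring.shape[0]
    if nb < 3:
        raise ValueError("contour needs at least 3 vertices")
    centroid = ring.mean(axis=0)
    vertices = np.vstack([ring, centroid])
    triangles = np.array([(i, (i + 1) % nb, nb) for i in range(nb)], dtype=np.int64)
    boundary = np.zeros(nb + 1, dtype=bool)
    boundary[:nb] = True
    for _ in range(n_refine):
        vertices, triangles, boundary = _refine(vertices, triangles, boundary)
    free = ~boundary
    area = float(triangle_areas(vertices, triangles).sum())
    step = 0.2 * max(np.linalg.norm(ring - centroid, axis=1).mean(), 1e-12)
    converged = False
    for _ in range(max_sweeps):
        grad = _area_gradient(vertices, triangles)
        grad[boundary] = 0.0
        gmax = np.abs(grad).max()
        if gmax < 1e-14:
            converged = True
            break
        # backtracking line search on the global step
        while step > 1e-12:
            trial = vertices.copy()
            trial[free] -= step * grad[free]
            new_area = float(triangle_areas(trial, triangles).sum())
            if new_area < area:
                break
            step *= 0.5
        else:
            converged = True
            break
        vertices = trial
        rel = (area - new_area) / max(area, 1e-300)
        area = new_area
        step *= 1.2
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn("minimal-surface relaxation did not converge; "
                      "returning best-effort mesh", RuntimeWarning)
    return SurfaceMesh(vertices=vertices, triangles=triangles,
                       boundary_mask=boundary, area=area, converged=converged)


def count_piercings(surface: SurfaceMesh, other_ring: np.ndarray, *,
                    max_jitter: int = 8, seed: int = 0) -> int:
    """Number of transversal crossings of ``other_ring``'s bonds with the surface.

    Each geometric crossing is counted once (strict interior tests exclude
    shared triangle edges).  Intersections landing exactly on a triangle edge
    or vertex are resolved by a deterministic, seeded 1e-9 sigma jitter of the
    probing contour and a retry, so the count is always defined and
    reproducible.
    """
    other_ring = np.asarray(other_ring, dtype=float)
    seg_a = other_ring
    seg_b = np.roll(other_ring, -1, axis=0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 777]))
    for attempt in range(max_jitter + 1):
        count, degen = _engine.count_segment_triangle_crossings(
            surface.vertices, surface.triangles, seg_a, seg_b, 1e-11)
        if not degen:
            return int(count)
        jitter = 1e-9 * (1 + attempt) * rng.standard_normal(other_ring.shape)
        seg_a = other_ring + jitter
        seg_b = np.roll(seg_a, -1, axis=0)
    warnings.warn("piercing count still degenerate after jitter retries; "
                  "using last count", RuntimeWarning)
    return int(count)


def threading_matrix(frame: Frame, topo: Topology, *, n_refine: int = 2,
                     surfaces: Optional[list[SurfaceMesh]] = None) -> np.ndarray:
    """M x M crossing counts c[i, j]: bonds of ring j piercing ring i's surface."""
    M = topo.M
    if surfaces is None:
        surfaces = [build_minimal_surface(frame.positions[topo.ring_slice(i)],
                                          n_refine=n_refine)
                    for i in range(M)]
    c = np.zeros((M, M), dtype=int)
    for i in range(M):
        for j in range(M):
            if i == j:
                continue
            c[i, j] = count_piercings(surfaces[i],
                                      frame.positions[topo.ring_slice(j)],
                                      seed=i * M + j)
    return c


def threaded_neighbors(frame: Frame, topo: Topology, *, n_refine: int = 2,
                       matrix: Optional[np.ndarray] = None,
                       ) -> tuple[np.ndarray, float]:
    """Per-ring number of threading partners and the system mean.

    Rings i and j are partners when either pierces the other's minimal
    surface (c[i, j] >= 1 or c[j, i] >= 1), so the relation is symmetric.
    """
    c = threading_matrix(frame, topo, n_refine=n_refine) if matrix is None else matrix
    partners = (c >= 1) | (c.T >= 1)
    np.fill_diagonal(partners, False)
    n_tn = partners.sum(axis=1)
    return n_tn, float(n_tn.mean())


def gauss_linking_number(ring_a: np.ndarray, ring_b: np.ndarray,
                         ) -> tuple[int, float]:
    """Gauss linking number of two closed polygonal curves.

    Returns ``(Lk, residual)`` where Lk is the nearest integer to the
    discrete Gauss double integral and residual the rounding remainder; a
    residual above 0.1 triggers a numerical-quality warning.
    """
    ring_a = np.ascontiguousarray(ring_a, dtype=float)
    ring_b = np.ascontiguousarray(ring_b, dtype=float)
    raw = _engine.linking_number_sum(ring_a, ring_b) / (4.0 * np.pi)
    lk = int(round(raw))
    residual = abs(raw - lk)
    if residual > 0.1:
        warnings.warn(f"Gauss linking integral far from integer "
                      f"(residual {residual:.3f})", RuntimeWarning)
    return lk, residual
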