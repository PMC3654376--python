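"""Cortical surface geometry: patch tessellation, dipole orientation, Laplacian.

The cortical surface is represented as a triangulated mesh. For source
analysis it is divided into contiguous *patches* of roughly equal area
(~1 cm^2 by convention), each represented by a single equivalent dipole
whose orientation is the normalized area-weighted sum of the triangle
normals in the patch. The patch adjacency graph (patches sharing a mesh
edge) defines a discrete surface Laplacian W used as a smoothness penalty
in the inverse problem:

    w_ii = -1,  w_ij = 1/N_i for j a neighbor of i,  0 otherwise,

where N_i is the number of neighbors of patch i. Rows of W for patches
with at least one neighbor sum to zero, so W annihilates spatially
constant source patterns.
"""

from __future__ import annotations

import heapq
import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger("corticoh.geometry")

__all__ = [
    "CorticalMesh",
    "PatchTessellation",
    "LaplacianOperator",
    "tessellate_patches",
    "patch_orientation",
    "build_neighbors",
    "build_laplacian",
]

#: tolerance factor for degenerate (self-cancelling) patch orientations
DEGENERATE_TOL = 1e-6


@dataclass
class CorticalMesh:
    """Triangulated cortical surface.

    Parameters
    ----------
    vertices : (n_vertices, 3) float array
        Vertex coordinates in millimetres.
    triangles : (n_triangles, 3) int array
        Vertex-index triples with consistent winding order.
    hemisphere : (n_vertices,) array of {"left", "right"}
        Hemisphere label per vertex.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    hemisphere: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.hemisphere = np.asarray(self.hemisphere)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")
        if len(self.hemisphere) != len(self.vertices):
            raise ValueError("one hemisphere label per vertex required")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_cross(self) -> np.ndarray:
        """Un-normalized triangle normals (cross products), mm^2 units.

        The vector (b-a) x (c-a) has magnitude twice the triangle area and
        points along the winding-order normal.
        """
        a = self.vertices[self.triangles[:, 0]]
        b = self.vertices[self.triangles[:, 1]]
        c = self.vertices[self.triangles[:, 2]]
        return np.cross(b - a, c - a)

    def triangle_areas_cm2(self) -> np.ndarray:
        """Triangle areas in cm^2 (vertices are in mm)."""
        return 0.5 * np.linalg.norm(self.triangle_cross(), axis=1) / 100.0

    def total_area_cm2(self) -> float:
        return float(self.triangle_areas_cm2().sum())

    def triangle_hemisphere(self) -> np.ndarray:
        """Majority hemisphere label per triangle."""
        labs = self.hemisphere[self.triangles]  # (m, 3)
        n_left = (labs == "left").sum(axis=1)
        return np.where(n_left >= 2, "left", "right")

    def edge_map(self) -> dict[tuple[int, int], list[int]]:
        """Map from undirected edge (i<j) to the triangles containing it."""
        edges: dict[tuple[int, int], list[int]] = defaultdict(list)
        for t, (i, j, k) in enumerate(self.triangles):
            for u, v in ((i, j), (j, k), (k, i)):
                edges[(min(u, v), max(u, v))].append(t)
        return dict(edges)

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        if self.n_triangles == 0:
            raise ValueError("mesh has no triangles")
        if self.triangles.min() < 0 or self.triangles.max() >= self.n_vertices:
            raise ValueError("triangle index out of range")
        if np.any(self.triangle_areas_cm2() <= 0):
            raise ValueError("mesh contains zero-area triangles")
        for edge, tris in self.edge_map().items():
            if len(tris) > 2:
                raise ValueError(f"edge {edge} shared by {len(tris)} triangles; "
                                 "mesh is not edge-manifold")
        if not set(np.unique(self.hemisphere)) <= {"left", "right"}:
            raise ValueError("hemisphere labels must be 'left' or 'right'")

    def triangle_adjacency(self) -> dict[int, list[int]]:
        """Triangle -> triangles sharing an edge with it."""
        adj: dict[int, list[int]] = defaultdict(list)
        for tris in self.edge_map().values():
            if len(tris) == 2:
                t0, t1 = tris
                adj[t0].append(t1)
                adj[t1].append(t0)
        return {t: sorted(ns) for t, ns in adj.items()}


@dataclass
class PatchTessellation:
    """Partition of mesh triangles into contiguous equal-area patches."""

    patch_of_triangle: np.ndarray          # (n_triangles,) int patch ids
    patch_area: np.ndarray                 # (n_patches,) cm^2
    orientation: np.ndarray                # (n_patches, 3) unit vectors
    neighbors: dict[int, set[int]]
    hemisphere: np.ndarray                 # (n_patches,) {"left","right"}
    centroid: np.ndarray                   # (n_patches, 3) mm, area-weighted
    degenerate: np.ndarray = field(default=None)  # (n_patches,) bool

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.patch_area), dtype=bool)

    @property
    def n_patches(self) -> int:
        return len(self.patch_area)

    def triangles_of(self, patch: int) -> np.ndarray:
        return np.flatnonzero(self.patch_of_triangle == patch)


@dataclass
class LaplacianOperator:
    """Discrete surface Laplacian on the patch adjacency graph."""

    W: sp.csr_matrix

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def toarray(self) -> np.ndarray:
        return self.W.toarray()


def patch_orientation(mesh: CorticalMesh,
                      patch_triangles: np.ndarray) -> tuple[np.ndarray, bool]:
    """Equivalent-dipole orientation of a patch.

    Sums the (area-weighted) triangle normals of the patch and normalizes
    to unit length. Returns ``(unit_vector, degenerate)``; a patch whose
    normals cancel (norm below ``DEGENERATE_TOL`` x patch area) is flagged
    degenerate and an arbitrary +z axis is returned.
    """
    patch_triangles = np.asarray(patch_triangles, dtype=np.int64)
    if patch_triangles.size == 0:
        raise ValueError("patch must contain at least one triangle")
    cross = mesh.triangle_cross()[patch_triangles]
    vec = cross.sum(axis=0)
    area_mm2 = 0.5 * np.linalg.norm(cross, axis=1).sum()
    norm = np.linalg.norm(vec)
    if norm < DEGENERATE_TOL * area_mm2:
        return np.array([0.0, 0.0, 1.0]), True
    return vec / norm, False


def _farthest_point_seeds(adj: dict[int, list[int]], n_triangles: int,
                          n_seeds: int, rng: np.random.Generator) -> list[int]:
    """Farthest-point sampling of seed triangles by graph hop distance.

    Deterministic given the RNG state: the first seed is drawn from the
    RNG, each later seed maximizes hop distance to all previous seeds
    (smallest index on ties).
    """
    first = int(rng.integers(n_triangles))
    seeds = [first]
    dist = np.full(n_triangles, np.iinfo(np.int64).max, dtype=np.int64)

    def relax(src: int) -> None:
        # BFS that lowers the min-distance-to-any-seed field
        queue = [src]
        dist[src] = 0
        d = 0
        while queue:
            nxt = []
            for t in queue:
                for u in adj.get(t, ()):
                    if dist[u] > d + 1:
                        dist[u] = d + 1
                        nxt.append(u)
            queue = nxt
            d += 1

    relax(first)
    while len(seeds) < n_seeds:
        far = int(np.argmax(dist))
        if dist[far] == 0:
            break  # graph smaller than seed count
        seeds.append(far)
        relax(far)
    return seeds


def tessellate_patches(mesh: CorticalMesh, target_area_cm2: float,
                       seed: int = 0) -> PatchTessellation:
    """Partition the mesh into contiguous patches of ~``target_area_cm2``.

    Greedy region growing on the triangle adjacency graph: seed triangles
    are placed by farthest-point sampling, then patches grow one triangle
    at a time, always extending the currently smallest patch, which keeps
    areas balanced around ``total_area / n_patches``. Disconnected mesh
    components that no seed reaches get their own patches.

    Parameters
    ----------
    mesh : CorticalMesh
    target_area_cm2 : float
        Desired patch area; the patch count is ``round(total/target)``.
    seed : int
        Seed for the farthest-point start triangle (default 0).
    """
    if target_area_cm2 <= 0:
        raise ValueError("target_area_cm2 must be positive")
    mesh.validate()
    areas = mesh.triangle_areas_cm2()
    total = float(areas.sum())
    if target_area_cm2 >= total:
        logger.warning("target area %.3g cm^2 >= total mesh area %.3g cm^2; "
                       "returning a single patch", target_area_cm2, total)
        n_patches = 1
    else:
        n_patches = max(1, int(round(total / target_area_cm2)))

    adj = mesh.triangle_adjacency()
    rng = np.random.default_rng(seed)
    seeds = _farthest_point_seeds(adj, mesh.n_triangles, n_patches, rng)

    assign = np.full(mesh.n_triangles, -1, dtype=np.int64)
    patch_area = np.zeros(len(seeds))
    frontiers: list[set[int]] = []
    heap: list[tuple[float, int]] = []
    for p, s in enumerate(seeds):
        assign[s] = p
        patch_area[p] = areas[s]
        frontiers.append(set(adj.get(s, ())))
        heapq.heappush(heap, (patch_area[p], p))

    while heap:
        area_p, p = heapq.heappop(heap)
        if area_p != patch_area[p]:
            continue  # stale entry
        cand = sorted(t for t in frontiers[p] if assign[t] == -1)
        frontiers[p] = set(cand)
        if not cand:
            continue
        t = cand[0]
        assign[t] = p
        patch_area[p] += areas[t]
        frontiers[p].discard(t)
        frontiers[p].update(u for u in adj.get(t, ()) if assign[u] == -1)
        heapq.heappush(heap, (patch_area[p], p))

    # any triangles unreached by region growing live in separate mesh
    # components: give each component its own patch
    leftover = np.flatnonzero(assign == -1)
    while leftover.size:
        p = len(patch_area)
        patch_area = np.append(patch_area, 0.0)
        stack = [int(leftover[0])]
        assign[stack[0]] = p
        while stack:
            t = stack.pop()
            patch_area[p] += areas[t]
            for u in adj.get(t, ()):
                if assign[u] == -1:
                    assign[u] = p
                    stack.append(u)
        leftover = np.flatnonzero(assign == -1)

    _balance_areas(assign, areas, adj, total / len(patch_area))
    patch_area = np.bincount(assign, weights=areas,
                             minlength=len(patch_area))
    n_patches = len(patch_area)
    orientation = np.zeros((n_patches, 3))
    degenerate = np.zeros(n_patches, dtype=bool)
    centroid = np.zeros((n_patches, 3))
    tri_hemi = mesh.triangle_hemisphere()
    hemisphere = np.empty(n_patches, dtype=object)
    tri_centers = mesh.vertices[mesh.triangles].mean(axis=1)
    for p in range(n_patches):
        tris = np.flatnonzero(assign == p)
        orientation[p], degenerate[p] = patch_orientation(mesh, tris)
        if degenerate[p]:
            logger.warning("patch %d has a degenerate (self-cancelling) "
                           "orientation; using +z", p)
        w = areas[tris]
        centroid[p] = (tri_centers[tris] * w[:, None]).sum(axis=0) / w.sum()
        left_area = w[tri_hemi[tris] == "left"].sum()
        hemisphere[p] = "left" if left_area >= w.sum() / 2 else "right"

    tess = PatchTessellation(
        patch_of_triangle=assign,
        patch_area=patch_area,
        orientation=orientation,
        neighbors={},
        hemisphere=hemisphere.astype(str),
        centroid=centroid,
        degenerate=degenerate,
    )
    tess.neighbors = build_neighbors(tess, mesh)
    return tess


def _balance_areas(assign: np.ndarray, areas: np.ndarray,
                   adj: dict[int, list[int]], target: float,
                   max_passes: int = 200) -> None:
    """Equalize patch areas by moving boundary triangles in place.

    Greedy growth can strand patches well below the target area when they
    get enclosed early. This pass repeatedly moves one boundary triangle
    from the most oversized neighbor into the most undersized patch (and
    vice versa) whenever the move reduces the area imbalance and keeps
    the donor edge-connected.
    """
    n_patches = int(assign.max()) + 1
    tris_of: list[set[int]] = [set() for _ in range(n_patches)]
    for t, p in enumerate(assign):
        tris_of[p].add(int(t))
    area_of = np.array([areas[list(s)].sum() if s else 0.0 for s in tris_of])

    def connected_without(q: int, t: int) -> bool:
        rest = tris_of[q] - {t}
        if not rest:
            return False
        start = next(iter(rest))
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in adj.get(u, ()):
                if v in rest and v not in seen:
                    seen.add(v)
                    stack.append(v)
        return len(seen) == len(rest)

    def try_transfer(p: int) -> bool:
        """Move one triangle from p's largest heavier neighbor into p."""
        best = None
        for t in sorted(tris_of[p]):
            for u in adj.get(t, ()):
                q = int(assign[u])
                if q == p:
                    continue
                a_t = areas[u]
                # move must strictly shrink the pairwise imbalance
                if area_of[q] - a_t <= area_of[p]:
                    continue
                if best is None or area_of[q] > area_of[best[1]]:
                    if connected_without(q, u):
                        best = (u, q)
        if best is None:
            return False
        u, q = best
        tris_of[q].discard(u)
        tris_of[p].add(u)
        assign[u] = p
        area_of[q] -= areas[u]
        area_of[p] += areas[u]
        return True

    for _ in range(max_passes):
        moved = False
        order = np.argsort(area_of)
        for p in order:
            if area_of[p] >= 0.75 * target:
                break
            moved |= try_transfer(int(p))
        for p in order[::-1]:
            if area_of[p] <= 1.5 * target:
                break
            # donate: treat the smallest neighbor as the receiver
            receivers = sorted({int(assign[u]) for t in tris_of[p]
                                for u in adj.get(t, ())
                                if assign[u] != p},
                               key=lambda q: area_of[q])
            for q in receivers:
                if area_of[q] < area_of[p]:
                    moved |= try_transfer(q)
                    break
        if not moved:
            break


def build_neighbors(tess: PatchTessellation, mesh: CorticalMesh,
                    allow_cross_hemisphere: bool = False) -> dict[int, set[int]]:
    """Patch adjacency: patches are neighbors iff they share a mesh edge.

    By default adjacency does not cross the hemisphere boundary (a
    surface-smoothness penalty should not tie the two hemispheres through
    the interhemispheric fissure); set ``allow_cross_hemisphere`` to relax.
    """
    assign = tess.patch_of_triangle
    neighbors: dict[int, set[int]] = {p: set() for p in range(tess.n_patches)}
    for tris in mesh.edge_map().values():
        if len(tris) != 2:
            continue
        a, b = int(assign[tris[0]]), int(assign[tris[1]])
        if a == b:
            continue
        if not allow_cross_hemisphere and tess.hemisphere[a] != tess.hemisphere[b]:
            continue
        neighbors[a].add(b)
        neighbors[b].add(a)
    return neighbors


def build_laplacian(neighbors: dict[int, set[int]]) -> LaplacianOperator:
    """Build W with w_ii = -1 and w_ij = 1/N_i for neighbors j of i.

    N_i is the neighbor count of patch i, so W is generally not symmetric.
    Isolated patches (N_i = 0) get a row of just -1 on the diagonal, which
    penalizes their amplitude directly; a warning is logged.
    """
    n = len(neighbors)
    rows, cols, vals = [], [], []
    for i in range(n):
        ns = neighbors[i]
        for j in ns:
            if i not in neighbors[j]:
                raise ValueError(f"neighbor map not symmetric at ({i}, {j})")
        rows.append(i)
        cols.append(i)
        vals.append(-1.0)
        if not ns:
            logger.warning("patch %d is isolated; Laplacian row penalizes "
                           "its amplitude directly", i)
            continue
        w = 1.0 / len(ns)
        for j in sorted(ns):
            rows.append(i)
            cols.append(j)
            vals.append(w)
    W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return LaplacianOperator(W=W)
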