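"""Triangle-mesh utilities shared across the pipeline.

Meshes are ``trimesh.Trimesh`` objects throughout (vertices in mm,
right-handed frame).  This module adds the pieces the pipeline needs beyond
stock trimesh: linear icosahedron subdivision (the SPHARM sampling topology),
genus-0 validation, Taubin lambda/mu smoothing with boundary vertices pinned,
and exact vectorized point-to-triangle closest-point distances.
"""

from __future__ import annotations

import numpy as np
import trimesh

__all__ = [
    "TopologyError",
    "linear_icosphere",
    "validate_genus_zero",
    "taubin_smooth",
    "closest_point_distances",
    "vertex_adjacency",
]


class TopologyError(ValueError):
    """Raised when a mesh is not a closed genus-0 manifold."""


def linear_icosphere(level: int, radius: float = 1.0) -> trimesh.Trimesh:
    """Unit icosahedron with each edge linearly subdivided into level+1 parts.

    Vertex count is 10 (level+1)^2 + 2: level 0 is the plain icosahedron
    (12 vertices); level 15 gives 2562 sphere directions.  Vertices are
    projected onto the sphere of the given radius.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    ico = trimesh.creation.icosahedron()
    base_v = np.asarray(ico.vertices, dtype=float)
    base_f = np.asarray(ico.faces, dtype=int)
    m = level + 1
    verts: list[np.ndarray] = []
    faces: list[tuple[int, int, int]] = []
    index: dict[tuple, int] = {}

    def vid(key: tuple, point: np.ndarray) -> int:
        j = index.get(key)
        if j is None:
            j = len(verts)
            index[key] = j
            verts.append(point)
        return j

    for a, b, c in base_f:
        # barycentric lattice on the face; keys canonicalized by the vertex
        # ids and integer weights so shared edges dedupe exactly
        ids = np.empty((m + 1, m + 1), dtype=int)
        for i in range(m + 1):
            for j in range(m + 1 - i):
                w = (m - i - j, i, j)
                corners = (int(a), int(b), int(c))
                # zero-weight corners dropped so points shared across
                # faces/edges get identical keys
                key = tuple(sorted((cn, wi) for cn, wi in zip(corners, w) if wi > 0))
                p = (w[0] * base_v[a] + w[1] * base_v[b] + w[2] * base_v[c]) / m
                ids[i, j] = vid(key, p)
        for i in range(m):
            for j in range(m - i):
                faces.append((ids[i, j], ids[i + 1, j], ids[i, j + 1]))
                if j < m - i - 1:
                    faces.append((ids[i + 1, j], ids[i + 1, j + 1], ids[i, j + 1]))
    V = np.asarray(verts, dtype=float)
    V = V / np.linalg.norm(V, axis=1)[:, None] * radius
    mesh = trimesh.Trimesh(vertices=V, faces=np.asarray(faces, dtype=int), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def validate_genus_zero(mesh: trimesh.Trimesh) -> None:
    """Require a closed genus-0 manifold (Euler characteristic 2, watertight)."""
    if not mesh.is_watertight:
        raise TopologyError("mesh has boundary edges (not watertight)")
    chi = int(mesh.euler_number)
    if chi != 2:
        raise TopologyError(f"mesh is not genus-0 (Euler characteristic {chi}, expected 2)")


def vertex_adjacency(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Per-vertex arrays of neighboring vertex indices."""
    n = len(mesh.vertices)
    neighbors: list[set] = [set() for _ in range(n)]
    for e0, e1 in mesh.edges_unique:
        neighbors[e0].add(int(e1))
        neighbors[e1].add(int(e0))
    return [np.fromiter(s, dtype=int) for s in neighbors]


def _boundary_vertices(mesh: trimesh.Trimesh) -> np.ndarray:
    if mesh.is_watertight:
        return np.zeros(len(mesh.vertices), dtype=bool)
    mask = np.zeros(len(mesh.vertices), dtype=bool)
    # edges on exactly one face are boundary
    edges = mesh.edges_sorted
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    boundary_edges = unique[counts == 1]
    mask[np.unique(boundary_edges)] = True
    return mask


def taubin_smooth(
    mesh: trimesh.Trimesh,
    lam: float = 0.5,
    mu: float = -0.53,
    steps: int = 10,
) -> trimesh.Trimesh:
    """Taubin smoothing: alternating lambda/mu uniform-Laplacian steps.

    The shrink step (lam > 0) alternates with an inflate step (mu < 0),
    suppressing the volume loss of plain Laplacian smoothing.  Boundary
    vertices of open meshes are pinned; face topology is unchanged.
    """
    import warnings

    if abs(lam) >= 1.0 or mu >= 0.0:
        warnings.warn(
            f"unusual Taubin parameters (lam={lam}, mu={mu}); expected |lam| < 1 and mu < 0",
            stacklevel=2,
        )
    V = np.asarray(mesh.vertices, dtype=float).copy()
    neighbors = vertex_adjacency(mesh)
    movable = ~_boundary_vertices(mesh)

    def laplacian(X: np.ndarray) -> np.ndarray:
        L = np.zeros_like(X)
        for i, nb in enumerate(neighbors):
            if movable[i] and nb.size:
                L[i] = X[nb].mean(axis=0) - X[i]
        return L

    for _ in range(steps):
        V = V + lam * laplacian(V)
        V = V + mu * laplacian(V)
    return trimesh.Trimesh(vertices=V, faces=np.asarray(mesh.faces).copy(), process=False)


def closest_point_distances(
    points: np.ndarray,
    mesh: trimesh.Trimesh,
    chunk: int = 2048,
    k_candidates: int = 24,
) -> np.ndarray:
    """Exact Euclidean distances from points to the closest point on a mesh.

    Point-to-triangle (not point-to-vertex): each query point is projected
    onto candidate triangles' faces/edges/vertices and the minimum is taken.
    Candidates come from a KD-tree over triangle centroids; a point's result
    is provably exact when the next centroid lies further than the candidate
    minimum plus the largest centroid-to-vertex radius — points failing that
    bound fall back to the full triangle set.  Degenerate (zero-area)
    triangles are skipped.
    """
    from scipy.spatial import cKDTree

    P = np.atleast_2d(np.asarray(points, dtype=float))
    tri = np.asarray(mesh.triangles, dtype=float)  # (t, 3, 3)
    areas = np.asarray(mesh.area_faces)
    good = areas > 0
    if not np.all(good):
        tri = tri[good]
    t = tri.shape[0]
    if t == 0:
        raise ValueError("reference mesh has no non-degenerate triangles")
    centroids = tri.mean(axis=1)
    r_max = float(np.max(np.linalg.norm(tri - centroids[:, None, :], axis=-1)))
    k = min(k_candidates, t)
    tree = cKDTree(centroids)
    out = np.empty(P.shape[0])
    for start in range(0, P.shape[0], chunk):
        Q = P[start : start + chunk]
        cdist, cidx = tree.query(Q, k=k)
        cdist, cidx = np.atleast_2d(cdist), np.atleast_2d(cidx)
        d = _point_candidate_triangle_distances(Q, tri[cidx])
        if k < t:
            # exactness bound: a triangle outside the candidate set has its
            # centroid at least cdist[:, -1] away, so its surface is at least
            # cdist[:, -1] - r_max away; points failing the bound are redone
            # against the full triangle set in small batches
            unsafe = np.flatnonzero(d > cdist[:, -1] - r_max)
            for ustart in range(0, unsafe.size, 64):
                block = unsafe[ustart : ustart + 64]
                d[block] = _point_candidate_triangle_distances(Q[block], tri[None])
        out[start : start + chunk] = d
    return out


def _point_candidate_triangle_distances(Q: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Min distance from each point Q[i] to its candidate triangles tris[i].

    ``Q`` is (q, 3); ``tris`` is (q, k, 3, 3) (or (1, k, 3, 3) broadcast).
    """
    if tris.shape[0] == 1 and Q.shape[0] > 1:
        tris = np.broadcast_to(tris, (Q.shape[0],) + tris.shape[1:])
    A, B, C = tris[:, :, 0], tris[:, :, 1], tris[:, :, 2]
    return _point_triangle_distance_block(Q, A, B, C)


def _point_triangle_distance_block(Q, A, B, C):
    """Min distance from each point to its candidate triangles (Ericson).

    ``Q`` is (q, 3); ``A``/``B``/``C`` are (q, k, 3) per-point candidates.
    """
    AB, AC = B - A, C - A
    P = Q[:, None, :]  # (q, 1, 3)
    AP = P - A
    d1 = np.sum(AB * AP, axis=-1)
    d2 = np.sum(AC * AP, axis=-1)
    BP = P - B
    d3 = np.sum(AB * BP, axis=-1)
    d4 = np.sum(AC * BP, axis=-1)
    CP = P - C
    d5 = np.sum(AB * CP, axis=-1)
    d6 = np.sum(AC * CP, axis=-1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    # vertex regions
    mA = (d1 <= 0) & (d2 <= 0)
    mB = (d3 >= 0) & (d4 <= d3)
    mC = (d6 >= 0) & (d5 <= d6)
    # edge regions
    denomAB = d1 - d3
    vAB = np.divide(d1, denomAB, out=np.zeros_like(d1), where=denomAB != 0)
    mAB = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denomAC = d2 - d6
    wAC = np.divide(d2, denomAC, out=np.zeros_like(d2), where=denomAC != 0)
    mAC = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denomBC = (d4 - d3) + (d5 - d6)
    wBC = np.divide(d4 - d3, denomBC, out=np.zeros_like(d4), where=denomBC != 0)
    mBC = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    # interior
    denom = va + vb + vc
    v = np.divide(vb, denom, out=np.zeros_like(vb), where=denom != 0)
    w = np.divide(vc, denom, out=np.zeros_like(vc), where=denom != 0)

    closest = A + v[..., None] * AB + w[..., None] * AC
    closest = np.where(mBC[..., None], B + wBC[..., None] * (C - B), closest)
    closest = np.where(mAC[..., None], A + wAC[..., None] * AC, closest)
    closest = np.where(mAB[..., None], A + vAB[..., None] * AB, closest)
    closest = np.where(mC[..., None], C, closest)
    closest = np.where(mB[..., None], B, closest)
    closest = np.where(mA[..., None], A, closest)

    dist = np.linalg.norm(P - closest, axis=-1)
    return dist.min(axis=1)
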