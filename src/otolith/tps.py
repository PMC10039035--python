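"""3D thin-plate-spline machinery and sliding semilandmarks.

The interpolating TPS in three dimensions uses the biharmonic kernel family
U(r) = -r (sign chosen so the bending-energy quadratic form is positive
semidefinite; the affine null space is unchanged).  The same machinery drives
mesh warping for soft-tissue reconstruction and the bending-energy criterion
under which semilandmarks slide along their curve tangents during
superimposition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .landmarks import AlignedShapeSet, gpa

__all__ = [
    "TpsWarp",
    "SemilandmarkCurve",
    "tps_fit",
    "warp_points",
    "warp_mesh",
    "bending_energy_matrix",
    "resample_equidistant",
    "slide_semilandmarks",
]

#: Tikhonov fallback regularization on the kernel matrix, used only when the
#: exact system is singular (near-degenerate, e.g. coplanar, sources).
DEFAULT_REGULARIZATION = 1e-8


def _kernel(r: np.ndarray) -> np.ndarray:
    return -r


@dataclass
class TpsWarp:
    """An interpolating 3D thin-plate spline fitted between two landmark sets.

    The map is f(q) = affine([1, q]) + sum_i w_i U(|q - s_i|); applying it to
    ``source_landmarks`` reproduces ``target_landmarks`` to solver tolerance.
    ``bending_energy`` is the non-affine deformation penalty (zero iff the
    target is an affine image of the source).
    """

    source_landmarks: np.ndarray  # (k, 3)
    target_landmarks: np.ndarray  # (k, 3)
    weights: np.ndarray  # (k, 3) non-affine coefficients
    affine: np.ndarray  # (4, 3); row 0 translation, rows 1-3 linear part
    bending_energy: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return warp_points(self, points)

    def to_json(self) -> str:
        return json.dumps(
            {
                "source_landmarks": self.source_landmarks.tolist(),
                "target_landmarks": self.target_landmarks.tolist(),
                "weights": self.weights.tolist(),
                "affine": self.affine.tolist(),
                "bending_energy": self.bending_energy,
                "kernel": "U(r) = -r",
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TpsWarp":
        d = json.loads(text)
        return cls(
            source_landmarks=np.asarray(d["source_landmarks"], dtype=float),
            target_landmarks=np.asarray(d["target_landmarks"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            affine=np.asarray(d["affine"], dtype=float),
            bending_energy=float(d["bending_energy"]),
        )


def _tps_lhs(source: np.ndarray, regularization: float) -> np.ndarray:
    k = source.shape[0]
    r = np.linalg.norm(source[:, None, :] - source[None, :, :], axis=-1)
    K = _kernel(r) + regularization * np.eye(k)
    P = np.hstack([np.ones((k, 1)), source])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    return L


def tps_fit(
    source: np.ndarray,
    target: np.ndarray,
    regularization: float = 0.0,
) -> TpsWarp:
    """Fit the interpolating thin-plate spline mapping source onto target.

    Requires k >= 4 source points; exactly duplicated source points make the
    system singular and are reported by index.  The system is solved exactly;
    if it is singular (near-coplanar sources), a Tikhonov-regularized solve
    (lambda = 1e-8) is used instead and the landmark interpolation becomes
    approximate at that tolerance.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
        raise ValueError(f"source/target must both be (k, 3); got {source.shape} and {target.shape}")
    k = source.shape[0]
    if k < 4:
        raise ValueError("TPS needs at least 4 landmarks")
    if not (np.all(np.isfinite(source)) and np.all(np.isfinite(target))):
        raise ValueError("non-finite landmark coordinates")
    r = np.linalg.norm(source[:, None, :] - source[None, :, :], axis=-1)
    dup = np.argwhere(np.triu(r < 1e-12, k=1))
    if dup.size:
        pairs = [tuple(map(int, p)) for p in dup]
        raise ValueError(f"duplicated source points (index pairs): {pairs}")

    rhs = np.zeros((k + 4, 3))
    rhs[:k] = target
    L = _tps_lhs(source, regularization)
    try:
        sol = np.linalg.solve(L, rhs)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError("non-finite solution")
    except np.linalg.LinAlgError:
        regularization = max(regularization, DEFAULT_REGULARIZATION)
        L = _tps_lhs(source, regularization)
        sol = np.linalg.solve(L, rhs)
    W, A = sol[:k], sol[k:]
    K = L[:k, :k] - regularization * np.eye(k)
    energy = float(np.trace(W.T @ K @ W))
    return TpsWarp(
        source_landmarks=source.copy(),
        target_landmarks=target.copy(),
        weights=W,
        affine=A,
        bending_energy=max(energy, 0.0),
    )


def warp_points(warp: TpsWarp, points: np.ndarray) -> np.ndarray:
    """Map arbitrary 3D query points through a fitted TPS."""
    q = np.asarray(points, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    r = np.linalg.norm(q[:, None, :] - warp.source_landmarks[None, :, :], axis=-1)
    out = np.hstack([np.ones((q.shape[0], 1)), q]) @ warp.affine + _kernel(r) @ warp.weights
    return out[0] if single else out


def warp_mesh(warp: TpsWarp, mesh):
    """Warp a trimesh.Trimesh through a TPS; faces are unchanged."""
    import trimesh

    vertices = warp_points(warp, np.asarray(mesh.vertices, dtype=float))
    return trimesh.Trimesh(vertices=vertices, faces=np.asarray(mesh.faces).copy(), process=False)


def bending_energy_matrix(reference: np.ndarray, regularization: float = 0.0) -> np.ndarray:
    """Bending-energy matrix E of a reference configuration (k x k, PSD).

    For any target Y (k x 3), tr(Y' E Y) is the TPS bending energy of the
    deformation from the reference to Y; affine deformations lie in E's null
    space.
    """
    reference = np.asarray(reference, dtype=float)
    k = reference.shape[0]
    try:
        E = np.linalg.inv(_tps_lhs(reference, regularization))[:k, :k]
    except np.linalg.LinAlgError:
        E = np.linalg.inv(
            _tps_lhs(reference, max(regularization, DEFAULT_REGULARIZATION))
        )[:k, :k]
    return (E + E.T) / 2.0


# ---------------------------------------------------------------------------
# curves and sliding
# ---------------------------------------------------------------------------

@dataclass
class SemilandmarkCurve:
    """An ordered run of semilandmarks sliding along one anatomical curve."""

    curve_id: str
    point_indices: np.ndarray  # ordered indices into the configuration
    anchors: bool = True  # first/last point fixed

    def __post_init__(self) -> None:
        self.point_indices = np.asarray(self.point_indices, dtype=int)
        if self.point_indices.size < 3:
            raise ValueError(f"curve {self.curve_id}: needs >= 3 points")
        if np.any(np.diff(self.point_indices) <= 0):
            raise ValueError(f"curve {self.curve_id}: indices must be strictly increasing")


def curves_from_set(aligned: AlignedShapeSet, anchors: bool = True) -> list[SemilandmarkCurve]:
    """Build SemilandmarkCurve descriptors from an aligned set's curve ids."""
    out = []
    seen: list[str] = []
    for c in aligned.curve_ids:
        if c is not None and c not in seen:
            seen.append(c)
    for cid in seen:
        idx = np.flatnonzero([c == cid for c in aligned.curve_ids])
        out.append(SemilandmarkCurve(curve_id=cid, point_indices=idx, anchors=anchors))
    return out


def resample_equidistant(curve_points: np.ndarray, n_out: int) -> np.ndarray:
    """Resample an ordered polyline to n_out points equidistant in arc length.

    Output points lie exactly on the input polyline; endpoints are preserved.
    """
    pts = np.asarray(curve_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("curve_points must be (m >= 2, 3)")
    if n_out < 2:
        raise ValueError("n_out must be >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0:
        raise ValueError("zero-length curve")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n_out)
    out = np.empty((n_out, 3))
    j = 0
    for i, t in enumerate(targets):
        while j < len(seg) - 1 and s[j + 1] < t:
            j += 1
        denom = seg[j] if seg[j] > 0 else 1.0
        alpha = (t - s[j]) / denom
        out[i] = pts[j] + np.clip(alpha, 0.0, 1.0) * (pts[j + 1] - pts[j])
    out[0], out[-1] = pts[0], pts[-1]
    return out


def _project_to_polyline(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Closest point on a piecewise-linear curve for each query point."""
    A = polyline[:-1]  # (s, 3)
    d = polyline[1:] - A
    L2 = np.sum(d * d, axis=1)
    L2[L2 == 0] = 1.0
    out = np.empty_like(points)
    for i, p in enumerate(points):
        t = np.clip(np.sum((p - A) * d, axis=1) / L2, 0.0, 1.0)
        cand = A + t[:, None] * d
        out[i] = cand[np.argmin(np.sum((cand - p) ** 2, axis=1))]
    return out


def _curve_tangents(points: np.ndarray, curve_id: str = "?") -> np.ndarray:
    """Unit tangents by central differences (one-sided at the ends)."""
    t = np.empty_like(points)
    t[1:-1] = points[2:] - points[:-2]
    t[0] = points[1] - points[0]
    t[-1] = points[-1] - points[-2]
    norms = np.linalg.norm(t, axis=1)
    bad = np.flatnonzero(norms < 1e-14)
    if bad.size:
        raise ValueError(
            f"curve {curve_id}: tangent undefined at point index {int(bad[0])} (coincident neighbors)"
        )
    return t / norms[:, None]


def total_bending_energy(aligned: AlignedShapeSet) -> float:
    """Summed TPS bending energy of every specimen relative to the consensus."""
    E = bending_energy_matrix(aligned.consensus)
    total = 0.0
    for i in range(aligned.n):
        Y = aligned.coords[i]
        total += float(np.trace(Y.T @ E @ Y))
    return max(total, 0.0)


def slide_semilandmarks(
    aligned: AlignedShapeSet,
    curves: list[SemilandmarkCurve] | None = None,
    max_iter: int = 5,
    tol: float = 1e-6,
    scale: bool = True,
) -> AlignedShapeSet:
    """Slide semilandmarks along curve tangents, minimizing bending energy.

    Per pass and per specimen, the semilandmarks of each curve are displaced
    along their local polyline tangents by the linearized (Gower/Bookstein
    style) bending-energy-minimizing update relative to the current consensus,
    snapped back onto the resampled curve polyline, and GPA is re-run.  Passes
    stop when the relative change in total bending energy drops below ``tol``
    or after ``max_iter`` passes.  Single landmarks never move.  Curve
    endpoints are fixed anchors by default.
    """
    if curves is None:
        curves = curves_from_set(aligned)
    if not curves:
        return aligned
    k = aligned.k
    for c in curves:
        if np.any(c.point_indices >= k) or np.any(c.point_indices < 0):
            raise ValueError(f"curve {c.curve_id}: indices out of range")

    current = aligned
    energy = total_bending_energy(current)
    trace = [energy]
    for _ in range(max_iter):
        E = bending_energy_matrix(current.consensus)
        new_coords = current.coords.copy()
        for i in range(current.n):
            Y = current.coords[i].copy()
            for c in curves:
                idx = c.point_indices
                pts = Y[idx]
                tangents = _curve_tangents(pts, c.curve_id)
                free = np.arange(1, len(idx) - 1) if c.anchors else np.arange(len(idx))
                if free.size == 0:
                    continue
                rows = idx[free]
                # minimize tr((Y + U t)' E (Y + U t)) over per-point slide
                # magnitudes t, with U t = t_j * tangent_j at row rows[j]
                T = tangents[free]  # (f, 3)
                Esub = E[np.ix_(rows, rows)]  # (f, f)
                G = (E @ Y)[rows]  # (f, 3) gradient/2 rows
                A = Esub * (T @ T.T)
                b = -np.sum(T * G, axis=1)
                t_sl, *_ = np.linalg.lstsq(
                    A + 1e-12 * np.eye(len(rows)), b, rcond=None
                )
                # cap slides at the local point spacing to stay in the
                # linearization's validity range
                spacing = np.linalg.norm(np.diff(pts, axis=0), axis=1)
                cap = np.empty(len(idx))
                cap[0], cap[-1] = spacing[0], spacing[-1]
                cap[1:-1] = np.minimum(spacing[:-1], spacing[1:])
                t_sl = np.clip(t_sl, -cap[free], cap[free])
                slid = pts.copy()
                slid[free] = pts[free] + t_sl[:, None] * T
                # snap slid points back onto the current curve polyline
                slid[free] = _project_to_polyline(slid[free], pts)
                if c.anchors:
                    slid[0], slid[-1] = pts[0], pts[-1]
                Y[idx] = slid
            new_coords[i] = Y
        configs = [
            current.configuration(i).with_points(new_coords[i]) for i in range(current.n)
        ]
        result = gpa(configs, scale=scale)
        new_energy = total_bending_energy(result)
        if new_energy > energy:  # sliding overshoot: keep previous state
            break
        rel_change = abs(energy - new_energy) / max(energy, 1e-300)
        current = result
        energy = new_energy
        trace.append(energy)
        if rel_change < tol:
            break
    current.ss_trace = list(current.ss_trace)
    current.energy_trace = trace  # type: ignore[attr-defined]
    return current
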