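"""Spherical-harmonic (SPHARM-PDM style) shape description of genus-0 meshes.

A closed genus-0 surface is mapped to the unit sphere, each Cartesian
coordinate is fitted as a real spherical-harmonic series up to degree L, and
shapes are compared/averaged through point-distribution-model (PDM) samples
taken at shared icosahedral sphere directions.  Correspondence across models
follows the first-order-ellipsoid convention: parameter spheres are rotated
so the degree-1 ellipsoid axes coincide.

Real basis convention (documented once, used everywhere): orthonormal real
spherical harmonics ordered l = 0..L, m = -l..l, without the Condon-Shortley
phase:

    m = 0:  Y_l0
    m > 0:  sqrt(2) (-1)^m Re(Y_l^m)
    m < 0:  sqrt(2) (-1)^m Im(Y_l^|m|)

Default per-structure degrees: vestibule 25, saccule 25, utricle 15 (the
utricle's oblong shape makes high-degree parametrizations unstable, so it is
capped lower).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.special import sph_harm_y_all

from .meshes import linear_icosphere, validate_genus_zero, vertex_adjacency
from .meshes import taubin_smooth  # noqa: F401  (re-exported: part of this stage)

__all__ = [
    "SpharmModel",
    "PdmSampling",
    "DEFAULT_DEGREES",
    "DEGREE_LADDER",
    "real_sph_harm_basis",
    "spherical_parametrize",
    "spharm_fit",
    "pdm_sample",
    "correspondence_align",
    "mean_shape",
    "degree_series_rmse",
    "count_flipped",
    "taubin_smooth",
]

#: Per-structure fitting degree defaults.
DEFAULT_DEGREES = {"vestibule": 25, "saccule": 25, "utricle": 15}

#: The degree series used when profiling reconstruction error against L.
DEGREE_LADDER = (1, 2, 3, 4, 5, 10, 15, 25)


def real_sph_harm_basis(degree: int, directions: np.ndarray) -> np.ndarray:
    """Real spherical-harmonic design matrix at unit-sphere directions.

    Returns an (n_points, (degree+1)^2) matrix with columns ordered
    (l ascending, m from -l to l).
    """
    u = np.asarray(directions, dtype=float)
    u = u / np.linalg.norm(u, axis=1)[:, None]
    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(u[:, 1], u[:, 0])  # azimuth
    Y = sph_harm_y_all(degree, degree, theta, phi)  # (L+1, 2L+1, n)
    cols = []
    sqrt2 = np.sqrt(2.0)
    for l in range(degree + 1):
        for m in range(-l, l + 1):
            am = abs(m)
            cs = (-1.0) ** am  # strip the Condon-Shortley phase
            if m == 0:
                cols.append(Y[l, 0].real)
            elif m > 0:
                cols.append(sqrt2 * cs * Y[l, am].real)
            else:
                cols.append(sqrt2 * cs * Y[l, am].imag)
    return np.column_stack(cols)


@dataclass
class SpharmModel:
    """Per-coordinate real spherical-harmonic coefficients up to degree L."""

    degree: int
    coeffs: np.ndarray  # (3, (L+1)^2)
    parametrization: np.ndarray  # per-vertex unit-sphere directions
    correspondence_rotation: np.ndarray = field(
        default_factory=lambda: np.eye(3)
    )  # rotation of the parameter sphere applied at sampling time
    rmse: float = 0.0
    voxel_spacing: float | None = None  # mm; provenance metadata only

    def evaluate(self, directions: np.ndarray) -> np.ndarray:
        """Surface points at given parameter-sphere directions."""
        u = np.asarray(directions, dtype=float) @ self.correspondence_rotation.T
        B = real_sph_harm_basis(self.degree, u)
        return B @ self.coeffs.T


@dataclass
class PdmSampling:
    """Corresponded PDM sample of one model at shared sphere directions."""

    subdivision_level: int
    sample_points: np.ndarray  # unit directions
    surface_points: np.ndarray  # mapped 3D points
    faces: np.ndarray  # subdivision topology

    def as_mesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.surface_points, faces=self.faces.copy(), process=False
        )


# ---------------------------------------------------------------------------
# parametrization
# ---------------------------------------------------------------------------

def count_flipped(directions: np.ndarray, faces: np.ndarray) -> int:
    """Number of spherical triangles with inward (flipped) orientation."""
    u = directions
    tri = u[faces]  # (t, 3, 3)
    det = np.einsum(
        "ti,ti->t", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])
    )
    return int(np.sum(det <= 0))


def spherical_parametrize(
    mesh: trimesh.Trimesh,
    max_iter: int = 200,
    relax: float = 0.5,
) -> np.ndarray:
    """Map a closed genus-0 mesh's vertices onto the unit sphere.

    Initial map: unit offsets from the volume centroid (exact for star-shaped
    surfaces).  If any spherical triangle is flipped, damped spherical
    Laplacian relaxation (average of neighbors, reprojected to the sphere) is
    iterated until no triangle is flipped.  Returns per-vertex unit
    directions; raises TopologyError for open or non-genus-0 meshes.
    """
    validate_genus_zero(mesh)
    center = mesh.center_mass
    V = np.asarray(mesh.vertices, dtype=float) - center
    norms = np.linalg.norm(V, axis=1)
    if np.any(norms < 1e-12):
        center = V.mean(axis=0) + center + 1e-6
        V = np.asarray(mesh.vertices, dtype=float) - center
        norms = np.linalg.norm(V, axis=1)
    # ellipsoid-adjusted radial projection: normalizing by the second-moment
    # ellipsoid before projecting spreads parameter density evenly over
    # flattened shapes and makes parametrizations consistent across
    # affinely-related specimens (better point correspondence downstream)
    C = V.T @ V / V.shape[0]
    evals, evecs = np.linalg.eigh(C)
    W = V @ evecs / np.sqrt(np.maximum(evals, 1e-12))
    W = W @ evecs.T  # back to the original axes, anisotropy removed
    U = W / np.linalg.norm(W, axis=1)[:, None]
    faces = np.asarray(mesh.faces, dtype=int)
    if count_flipped(U, faces) == 0:
        return U
    neighbors = vertex_adjacency(mesh)
    for _ in range(max_iter):
        mean_nb = np.stack([U[nb].mean(axis=0) for nb in neighbors])
        U = (1.0 - relax) * U + relax * mean_nb
        nrm = np.linalg.norm(U, axis=1)
        if np.any(nrm < 1e-12):
            raise ValueError("spherical relaxation collapsed; mesh too far from star-shaped")
        U = U / nrm[:, None]
        if count_flipped(U, faces) == 0:
            return U
    raise ValueError(
        f"parametrization did not untangle after {max_iter} relaxation sweeps "
        f"({count_flipped(U, faces)} flipped triangles remain)"
    )


def _spherical_vertex_areas(directions: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-vertex Voronoi-style areas on the parameter sphere (1/3 incident)."""
    tri = directions[faces]
    # flat-triangle area of the spherical triangle chords: adequate weighting
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    fa = 0.5 * np.linalg.norm(cross, axis=1)
    areas = np.zeros(directions.shape[0])
    np.add.at(areas, faces.ravel(), np.repeat(fa / 3.0, 3))
    return areas


def spharm_fit(
    mesh: trimesh.Trimesh,
    parametrization: np.ndarray,
    degree: int,
    voxel_spacing: float | None = None,
) -> SpharmModel:
    """Weighted least-squares SPHARM fit of a mesh's coordinate functions.

    Each Cartesian coordinate is fitted over the vertices as a degree-L real
    spherical-harmonic series, weighted by per-vertex area on the parameter
    sphere to reduce sampling bias.  Requires (L+1)^2 <= number of vertices.
    """
    V = np.asarray(mesh.vertices, dtype=float)
    U = np.asarray(parametrization, dtype=float)
    if U.shape != V.shape:
        raise ValueError("parametrization must be one unit direction per vertex")
    nb = (degree + 1) ** 2
    if nb > V.shape[0]:
        raise ValueError(
            f"underdetermined fit: degree {degree} needs {nb} <= {V.shape[0]} vertices; "
            "lower the degree"
        )
    B = real_sph_harm_basis(degree, U)
    w = _spherical_vertex_areas(U, np.asarray(mesh.faces, dtype=int))
    sw = np.sqrt(np.maximum(w, 1e-300))
    coeffs, *_ = np.linalg.lstsq(B * sw[:, None], V * sw[:, None], rcond=None)
    resid = B @ coeffs - V
    rmse = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return SpharmModel(
        degree=degree,
        coeffs=coeffs.T.copy(),
        parametrization=U.copy(),
        rmse=rmse,
        voxel_spacing=voxel_spacing,
    )


def pdm_sample(model: SpharmModel, subdivision_level: int = 15) -> PdmSampling:
    """Evaluate the harmonic series at icosahedral-subdivision directions.

    Identical subdivision levels give identical sample directions across
    models — the correspondence contract of the PDM.
    """
    sphere = linear_icosphere(subdivision_level)
    directions = np.asarray(sphere.vertices, dtype=float)
    surface = model.evaluate(directions)
    return PdmSampling(
        subdivision_level=subdivision_level,
        sample_points=directions,
        surface_points=surface,
        faces=np.asarray(sphere.faces, dtype=int),
    )


# ---------------------------------------------------------------------------
# correspondence and means
# ---------------------------------------------------------------------------

def _degree1_linear_map(model: SpharmModel) -> np.ndarray:
    """3x3 matrix M with degree-1 surface contribution f1(u) = M u."""
    idx = [1, 2, 3]  # (l=1, m=-1,0,1)
    eye = np.eye(3)
    B1 = real_sph_harm_basis(1, eye)[:, idx]  # (3 dirs, 3 funcs)
    C1 = model.coeffs[:, idx]  # (3 coords, 3 funcs)
    # f1(e_i) = C1 @ B1[i]; M columns are f1(e_i)
    return C1 @ B1.T


def _refit_rotated(model: SpharmModel, R: np.ndarray) -> SpharmModel:
    """Bake a parameter-sphere rotation into the coefficients.

    The rotated function u -> f(R u) is still band-limited at the same
    degree, so a dense least-squares refit recovers its coefficients exactly
    (up to solver tolerance); Wigner rotation matrices are not needed.
    """
    level = 15 if model.degree <= 25 else int(np.ceil(np.sqrt((model.degree + 1) ** 2 / 5)))
    sphere = linear_icosphere(level)
    u = np.asarray(sphere.vertices, dtype=float)
    target = model.evaluate(u @ R.T)
    B = real_sph_harm_basis(model.degree, u)
    coeffs, *_ = np.linalg.lstsq(B, target, rcond=None)
    return SpharmModel(
        degree=model.degree,
        coeffs=coeffs.T.copy(),
        parametrization=model.parametrization.copy(),
        correspondence_rotation=np.eye(3),
        rmse=model.rmse,
        voxel_spacing=model.voxel_spacing,
    )


def correspondence_align(models: list[SpharmModel]) -> list[SpharmModel]:
    """Rotate parameter spheres so degree-1 ellipsoid axes align across models.

    The first model's parametrization is the reference; every other model's
    parameter sphere is rotated by the proper rotation that best maps its
    degree-1 linear map onto the reference's (an orthogonal Procrustes fit of
    the two first-order ellipsoids).  This avoids per-model axis ordering and
    sign decisions, which are unstable when two ellipsoid axes are nearly
    equal.  Models whose degree-1 part is degenerate (nearly spherical) are
    returned unchanged with a warning.  The rotation is baked into the
    returned coefficients (correspondence_rotation = identity), so
    parameter-rotated copies of one shape come back with equal coefficient
    vectors.
    """
    if len(models) < 2:
        raise ValueError("alignment needs at least 2 models")
    degrees = {m.degree for m in models}
    if len(degrees) != 1:
        raise ValueError(f"models have mixed degrees: {sorted(degrees)}")
    M_ref = _degree1_linear_map(models[0])
    out = [models[0]]
    for model in models[1:]:
        M = _degree1_linear_map(model)
        s = np.linalg.svd(M, compute_uv=False)
        if s[0] <= 0 or (s[0] - s[2]) / s[0] < 1e-6:
            warnings.warn(
                "degenerate (spherical) degree-1 part; correspondence left as identity",
                stacklevel=2,
            )
            out.append(model)
            continue
        # proper rotation R minimizing ||M R - M_ref||_F
        U, _, Vt = np.linalg.svd(M.T @ M_ref)
        d = np.sign(np.linalg.det(U @ Vt))
        R = U @ np.diag([1.0, 1.0, d]) @ Vt
        if np.allclose(R, np.eye(3), atol=1e-12):
            out.append(model)
            continue
        out.append(_refit_rotated(model, R))
    return out


def mean_shape(models: list[SpharmModel], subdivision_level: int = 15) -> trimesh.Trimesh:
    """Pointwise-average PDM of corresponded models, as a triangle mesh."""
    if not models:
        raise ValueError("no models given")
    degrees = {m.degree for m in models}
    if len(degrees) != 1:
        raise ValueError(f"models have mixed degrees: {sorted(degrees)}")
    samples = [pdm_sample(m, subdivision_level) for m in models]
    pts = np.mean([s.surface_points for s in samples], axis=0)
    return trimesh.Trimesh(vertices=pts, faces=samples[0].faces.copy(), process=False)


def degree_series_rmse(
    mesh: trimesh.Trimesh,
    parametrization: np.ndarray,
    degrees: tuple[int, ...] = DEGREE_LADDER,
) -> dict[int, float]:
    """Reconstruction RMSE at each degree of the fitting ladder."""
    return {
        L: spharm_fit(mesh, parametrization, L).rmse
        for L in degrees
        if (L + 1) ** 2 <= len(mesh.vertices)
    }
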