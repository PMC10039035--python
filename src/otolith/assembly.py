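"""Assembly of the morphometric model of the otolith system.

The model combines mean SPHARM meshes (shape) with the consensus landmark
configuration (position, orientation, scale): each mean mesh carries fiducial
landmarks, a closed-form similarity transform registers it onto the matching
consensus landmarks, macular wireframes are built from the consensus
semilandmark contours, and the perilymphatic "negative space" mesh (vestibule
volume minus the membranous organs) is extracted by voxel boolean operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from skimage import measure

from .landmarks import AlignedShapeSet, LandmarkConfiguration

__all__ = [
    "SimilarityTransform",
    "MorphometricModel",
    "fit_similarity",
    "assemble_model",
    "build_perilymph_mesh",
    "ContainmentError",
]


class ContainmentError(ValueError):
    """Raised when the membranous organs are not inside the bony vestibule."""


@dataclass
class SimilarityTransform:
    """Closed-form least-squares similarity: x -> scale * (x @ rotation) + translation."""

    scale: float
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray
    rms_fiducial_error: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(points, dtype=float) @ self.rotation) + self.translation

    def apply_mesh(self, mesh: trimesh.Trimesh) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.apply(mesh.vertices),
            faces=np.asarray(mesh.faces).copy(),
            process=False,
        )


def fit_similarity(source_fiducials: np.ndarray, target_fiducials: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity (rotation + isotropic scale + translation).

    Umeyama-style closed form via the cross-covariance SVD; reflections are
    excluded.  Needs k >= 3 non-collinear fiducial pairs.
    """
    S = np.asarray(source_fiducials, dtype=float)
    T = np.asarray(target_fiducials, dtype=float)
    if S.shape != T.shape or S.ndim != 2 or S.shape[1] != 3 or S.shape[0] < 3:
        raise ValueError("need matched (k >= 3, 3) fiducial arrays")
    mu_s, mu_t = S.mean(axis=0), T.mean(axis=0)
    Sc, Tc = S - mu_s, T - mu_t
    if np.linalg.matrix_rank(Sc) < 2:
        raise ValueError("collinear fiducials: similarity transform is not determined")
    H = Sc.T @ Tc
    U, sv, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    scale = float(np.sum((Sc @ R) * Tc) / np.sum(Sc**2))
    t = mu_t - scale * (mu_s @ R)
    resid = scale * (Sc @ R) - Tc
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return SimilarityTransform(scale=scale, rotation=R, translation=t, rms_fiducial_error=rms)


@dataclass
class MorphometricModel:
    """Mean meshes, consensus landmarks, macular wireframes and perilymph mesh.

    All components are expressed in the consensus landmark frame.  The
    perilymph mesh carries the bony landmarks LM1-LM10, so reconstructing a
    new specimen's membranous organs needs only that specimen's bony
    landmarks.
    """

    mean_vestibule: trimesh.Trimesh
    mean_utricle: trimesh.Trimesh
    mean_saccule: trimesh.Trimesh
    consensus_landmarks: LandmarkConfiguration
    macular_wireframes: dict[str, np.ndarray]
    perilymph_mesh: trimesh.Trimesh | None
    perilymph_bony_landmarks: np.ndarray  # (10, 3), LM1..LM10 order
    bony_landmark_labels: list[str] = field(
        default_factory=lambda: [f"LM{i}" for i in range(1, 11)]
    )
    transforms: dict[str, SimilarityTransform] = field(default_factory=dict)
    voxel_size: float | None = None


#: Which consensus single landmarks serve as fiducials for each mean mesh.
MESH_FIDUCIAL_LABELS = {
    "vestibule": [f"LM{i}" for i in range(1, 11)],
    "utricle": ["LM11", "LM12", "LM13", "LM17", "LM18", "LM19"],
    "saccule": ["LM14", "LM15", "LM16", "LM20", "LM21", "LM22"],
}


def assemble_model(
    mean_meshes: dict[str, tuple[trimesh.Trimesh, dict[str, np.ndarray]]],
    consensus: LandmarkConfiguration | AlignedShapeSet,
    voxel_size: float | None = 0.05,
) -> MorphometricModel:
    """Register mean meshes onto the consensus landmark frame and assemble.

    Parameters
    ----------
    mean_meshes
        {"vestibule"/"utricle"/"saccule": (mesh, fiducials)} where fiducials
        maps landmark labels to 3D positions on (or near) that mean mesh.
    consensus
        The GPA consensus (single landmarks are matched to fiducials by
        label; semilandmark contours SemiLM4/SemiLM5, when present, become
        the macular wireframes).
    voxel_size
        Voxel pitch (mm) for the perilymphatic negative-space mesh; None
        skips the voxel boolean step.
    """
    cfg = (
        consensus.consensus_configuration()
        if isinstance(consensus, AlignedShapeSet)
        else consensus
    )
    registered: dict[str, trimesh.Trimesh] = {}
    transforms: dict[str, SimilarityTransform] = {}
    for name in ("vestibule", "utricle", "saccule"):
        if name not in mean_meshes:
            raise KeyError(f"mean mesh missing: {name!r}")
        mesh, fiducials = mean_meshes[name]
        labels = [l for l in MESH_FIDUCIAL_LABELS[name] if l in fiducials]
        if len(labels) < 3:
            raise ValueError(f"mesh {name!r}: needs >= 3 fiducials, has {len(labels)}")
        src = np.array([fiducials[l] for l in labels], dtype=float)
        tgt = np.array([cfg.points[cfg.index_of(l)] for l in labels], dtype=float)
        xf = fit_similarity(src, tgt)
        registered[name] = xf.apply_mesh(mesh)
        transforms[name] = xf

    wireframes: dict[str, np.ndarray] = {}
    for cid, key in (("SemiLM4", "utricular_macula"), ("SemiLM5", "saccular_macula")):
        try:
            idx = cfg.curve_indices(cid)
        except KeyError:
            continue
        wireframes[key] = cfg.points[idx].copy()

    bony = np.array(
        [cfg.points[cfg.index_of(f"LM{i}")] for i in range(1, 11)], dtype=float
    )
    peri = None
    if voxel_size is not None:
        peri = build_perilymph_mesh(
            registered["vestibule"], registered["utricle"], registered["saccule"],
            voxel_size=voxel_size,
        )
    return MorphometricModel(
        mean_vestibule=registered["vestibule"],
        mean_utricle=registered["utricle"],
        mean_saccule=registered["saccule"],
        consensus_landmarks=cfg,
        macular_wireframes=wireframes,
        perilymph_mesh=peri,
        perilymph_bony_landmarks=bony,
        transforms=transforms,
        voxel_size=voxel_size,
    )


def _solid_mask(mesh: trimesh.Trimesh, pitch: float, origin: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Rasterize a closed mesh into a filled boolean voxel grid on a common lattice."""
    vg = mesh.voxelized(pitch).fill()
    pts = vg.points  # centers of filled voxels, world frame
    idx = np.round((pts - origin) / pitch).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    mask = np.zeros(shape, dtype=bool)
    mask[idx[ok, 0], idx[ok, 1], idx[ok, 2]] = True
    return mask


def build_perilymph_mesh(
    vestibule: trimesh.Trimesh,
    utricle: trimesh.Trimesh | None,
    saccule: trimesh.Trimesh | None,
    voxel_size: float = 0.05,
    containment_tolerance: int = 0,
) -> trimesh.Trimesh:
    """Negative-space (perilymphatic) mesh by voxel boolean subtraction.

    All meshes are rasterized at ``voxel_size`` onto one lattice, organ
    voxels are subtracted from vestibule voxels, and the boundary surface of
    the remaining set is extracted by marching cubes.  Organ voxels falling
    outside the vestibule raise a containment error (counted).  The voxel
    count volume is attached as ``mesh.metadata['voxel_volume']``.
    """
    lo, hi = np.asarray(vestibule.bounds, dtype=float)
    margin = 3 * voxel_size
    origin = lo - margin
    shape = tuple(np.ceil((hi - lo + 2 * margin) / voxel_size).astype(int) + 1)
    vest = _solid_mask(vestibule, voxel_size, origin, shape)
    organs = np.zeros(shape, dtype=bool)
    outside = 0
    for organ in (utricle, saccule):
        if organ is None or len(organ.faces) == 0:
            continue
        m = _solid_mask(organ, voxel_size, origin, shape)
        outside += int(np.sum(m & ~vest))
        organs |= m
    if outside > containment_tolerance:
        raise ContainmentError(
            f"{outside} organ voxels lie outside the vestibule volume"
        )
    shell = vest & ~organs
    field = np.pad(shell.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=(voxel_size,) * 3)
    verts = verts + origin - voxel_size  # undo padding offset
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    mesh.metadata["voxel_volume"] = float(shell.sum()) * voxel_size**3
    mesh.metadata["voxel_size"] = voxel_size
    return mesh
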