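"""Landmark configurations and Procrustes superimposition.

The otolith-system landmarking scheme uses 22 single landmarks (LM1-LM10 on
the bony vestibule, LM11-LM22 on the membranous organs and maculae) plus five
sliding-semilandmark curves (SemiLM1-SemiLM5, 86 points in total).  This
module holds the configuration container, centroid size, ordinary Procrustes
alignment (OPA), generalized Procrustes analysis (GPA), and the
"within a configuration" block subsetting in which landmark subsets are taken
from the jointly superimposed coordinates without re-superimposition, so the
relative position and scale of bony and membranous subsets is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LandmarkConfiguration",
    "AlignedShapeSet",
    "LandmarkSetDefinition",
    "InvalidConfigurationError",
    "SINGLE_LANDMARKS",
    "SEMILANDMARK_CURVES",
    "centroid_size",
    "opa_align",
    "gpa",
    "subset_blocks",
    "landmark_set",
    "full_scheme_template",
]


class InvalidConfigurationError(ValueError):
    """Raised for degenerate or malformed landmark configurations."""


#: Single landmarks of the full scheme and their tissue block.
#: LM1-LM10 lie on the bony vestibule (membrana-limitans attachments,
#: oval-window margin, spherical-recess border, aqueductal point ...);
#: LM11-LM16 on the membranous utricle/saccule walls; LM17-LM19 form the
#: utricular macula triad and LM20-LM22 the saccular macula triad.
SINGLE_LANDMARKS: dict[str, str] = {f"LM{i}": ("bony" if i <= 10 else "membranous") for i in range(1, 23)}

#: Semilandmark curves: curve id -> (number of points, tissue block).
#: SemiLM1 traces the spherical-recess border and SemiLM2 the oval window
#: (both bony); SemiLM3 follows the membranous utricle contour, SemiLM4 the
#: utricular macula contour and SemiLM5 the saccular macula contour.
SEMILANDMARK_CURVES: dict[str, tuple[int, str]] = {
    "SemiLM1": (20, "bony"),
    "SemiLM2": (18, "bony"),
    "SemiLM3": (16, "membranous"),
    "SemiLM4": (16, "membranous"),
    "SemiLM5": (16, "membranous"),
}


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidConfigurationError(f"points must be (k, 3), got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise InvalidConfigurationError("non-finite coordinates in configuration")
    return pts


@dataclass
class LandmarkConfiguration:
    """One specimen's named 3D landmark configuration (coordinates in mm).

    Point order is the homology contract: index ``i`` refers to the same
    anatomical locus in every specimen.  Homology is validated by label
    equality, never by geometry.
    """

    specimen_id: str
    points: np.ndarray
    labels: list[str]
    roles: list[str]
    curve_ids: list[str | None]
    blocks: list[str]

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        k = self.points.shape[0]
        if k < 3:
            raise InvalidConfigurationError("configuration needs at least 3 points")
        for name, seq in (("labels", self.labels), ("roles", self.roles),
                          ("curve_ids", self.curve_ids), ("blocks", self.blocks)):
            if len(seq) != k:
                raise InvalidConfigurationError(f"{name} has length {len(seq)}, expected {k}")
        singles = [l for l, r in zip(self.labels, self.roles) if r == "single"]
        if len(set(singles)) != len(singles):
            raise InvalidConfigurationError("duplicate single-landmark labels")
        bad = [r for r in self.roles if r not in ("single", "semilandmark")]
        if bad:
            raise InvalidConfigurationError(f"unknown roles: {sorted(set(bad))}")
        for i, (r, c) in enumerate(zip(self.roles, self.curve_ids)):
            if r == "semilandmark" and c is None:
                raise InvalidConfigurationError(f"semilandmark at index {i} has no curve_id")
        # curve point order must be contiguous
        seen_done = set()
        prev = None
        for c in self.curve_ids:
            if c != prev and c is not None:
                if c in seen_done:
                    raise InvalidConfigurationError(f"curve {c} is not contiguous")
                seen_done.add(c)
            prev = c

    @property
    def k(self) -> int:
        return self.points.shape[0]

    def curve_indices(self, curve_id: str) -> np.ndarray:
        """Indices of the semilandmarks belonging to one curve, in order."""
        idx = np.flatnonzero([c == curve_id for c in self.curve_ids])
        if idx.size == 0:
            raise KeyError(f"no curve {curve_id!r} in configuration")
        return idx

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no landmark labelled {label!r}") from None

    def with_points(self, points: np.ndarray, specimen_id: str | None = None) -> "LandmarkConfiguration":
        """Copy of this configuration with replaced coordinates."""
        return LandmarkConfiguration(
            specimen_id=specimen_id or self.specimen_id,
            points=np.array(points, dtype=float),
            labels=list(self.labels),
            roles=list(self.roles),
            curve_ids=list(self.curve_ids),
            blocks=list(self.blocks),
        )


def full_scheme_template() -> tuple[list[str], list[str], list[str | None], list[str]]:
    """Labels/roles/curve ids/blocks of the full 22 + 86 = 108-point scheme."""
    labels: list[str] = []
    roles: list[str] = []
    curves: list[str | None] = []
    blocks: list[str] = []
    for lm, block in SINGLE_LANDMARKS.items():
        labels.append(lm)
        roles.append("single")
        curves.append(None)
        blocks.append(block)
    for cid, (npts, block) in SEMILANDMARK_CURVES.items():
        for j in range(npts):
            labels.append(f"{cid}_{j + 1:02d}")
            roles.append("semilandmark")
            curves.append(cid)
            blocks.append(block)
    return labels, roles, curves, blocks


@dataclass
class AlignedShapeSet:
    """GPA output: superimposed coordinates plus alignment metadata.

    ``coords`` has shape (n specimens, k points, 3); ``consensus`` is the
    pointwise mean of ``coords``; ``centroid_sizes`` are the pre-scaling
    centroid sizes in mm (used downstream for the size regressions).
    """

    coords: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    specimen_ids: list[str]
    labels: list[str]
    roles: list[str]
    curve_ids: list[str | None]
    blocks: list[str]
    iterations: int = 0
    converged: bool = True
    ss_trace: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def configuration(self, i: int) -> LandmarkConfiguration:
        """The i-th aligned specimen as a LandmarkConfiguration."""
        return LandmarkConfiguration(
            specimen_id=self.specimen_ids[i],
            points=self.coords[i].copy(),
            labels=list(self.labels),
            roles=list(self.roles),
            curve_ids=list(self.curve_ids),
            blocks=list(self.blocks),
        )

    def consensus_configuration(self) -> LandmarkConfiguration:
        return LandmarkConfiguration(
            specimen_id="consensus",
            points=self.consensus.copy(),
            labels=list(self.labels),
            roles=list(self.roles),
            curve_ids=list(self.curve_ids),
            blocks=list(self.blocks),
        )

    def take(self, indices: np.ndarray) -> "AlignedShapeSet":
        """Coordinate view restricted to a point subset, WITHOUT re-superimposition."""
        idx = np.asarray(indices, dtype=int)
        return AlignedShapeSet(
            coords=self.coords[:, idx, :],
            consensus=self.consensus[idx, :],
            centroid_sizes=self.centroid_sizes.copy(),
            specimen_ids=list(self.specimen_ids),
            labels=[self.labels[i] for i in idx],
            roles=[self.roles[i] for i in idx],
            curve_ids=[self.curve_ids[i] for i in idx],
            blocks=[self.blocks[i] for i in idx],
            iterations=self.iterations,
            converged=self.converged,
            ss_trace=list(self.ss_trace),
        )

    def flat(self) -> np.ndarray:
        """Coordinates flattened to (n, 3k) for multivariate statistics."""
        return self.coords.reshape(self.n, -1)


# ---------------------------------------------------------------------------
# landmark set definitions (sets 1-6 of the covariation analyses)
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSetDefinition:
    """A named selection of single landmarks and curves with a 2-module split.

    ``modules`` maps every included label to its module for the
    integration/modularity contrasts: tissue blocks (bony vs membranous) for
    sets 1-5, greater-utricle vs greater-saccule for set 6.
    """

    set_id: str
    included_singles: list[str]
    included_curves: list[str]
    modules: dict[str, str]

    def point_indices(self, labels: list[str], curve_ids: list[str | None]) -> np.ndarray:
        wanted = []
        missing = []
        include_curve = set(self.included_curves)
        include_single = set(self.included_singles)
        found_singles, found_curves = set(), set()
        for i, (lab, cid) in enumerate(zip(labels, curve_ids)):
            if cid is not None and cid in include_curve:
                wanted.append(i)
                found_curves.add(cid)
            elif cid is None and lab in include_single:
                wanted.append(i)
                found_singles.add(lab)
        missing = sorted(include_single - found_singles) + sorted(include_curve - found_curves)
        if missing:
            raise KeyError(f"labels missing from configuration: {missing}")
        return np.asarray(wanted, dtype=int)

    def module_of(self, label: str, curve_id: str | None) -> str:
        key = curve_id if curve_id is not None else label
        return self.modules[key]


def _tissue_modules(singles: list[str], curves: list[str]) -> dict[str, str]:
    mods = {lm: SINGLE_LANDMARKS[lm] for lm in singles}
    mods.update({c: SEMILANDMARK_CURVES[c][1] for c in curves})
    return mods


def landmark_set(set_id: int | str) -> LandmarkSetDefinition:
    """The six predefined landmark sets of the covariation analyses.

    1. all 22 single landmarks + all five semilandmark curves;
    2. set 1 without the oval-window curve (SemiLM2);
    3. single landmarks only;
    4. set 3 without LM5 (highest intra-observer placement variance);
    5. set 4 without LM7 (anteriormost oval-window point);
    6. greater-utricle vs greater-saccule split (bony + membranous landmarks
       of each organ grouped together).
    """
    sid = str(set_id)
    all_singles = list(SINGLE_LANDMARKS)
    all_curves = list(SEMILANDMARK_CURVES)
    if sid == "1":
        s, c = all_singles, all_curves
        return LandmarkSetDefinition("1", s, c, _tissue_modules(s, c))
    if sid == "2":
        s, c = all_singles, [cc for cc in all_curves if cc != "SemiLM2"]
        return LandmarkSetDefinition("2", s, c, _tissue_modules(s, c))
    if sid == "3":
        return LandmarkSetDefinition("3", all_singles, [], _tissue_modules(all_singles, []))
    if sid == "4":
        s = [lm for lm in all_singles if lm != "LM5"]
        return LandmarkSetDefinition("4", s, [], _tissue_modules(s, []))
    if sid == "5":
        s = [lm for lm in all_singles if lm not in ("LM5", "LM7")]
        return LandmarkSetDefinition("5", s, [], _tissue_modules(s, []))
    if sid == "6":
        utricle_singles = [f"LM{i}" for i in (1, 2, 3, 4, 5, 6, 11, 12, 13, 17, 18, 19)]
        saccule_singles = [f"LM{i}" for i in (7, 8, 9, 10, 14, 15, 16, 20, 21, 22)]
        utricle_curves = ["SemiLM3", "SemiLM4"]
        saccule_curves = ["SemiLM1", "SemiLM2", "SemiLM5"]
        mods: dict[str, str] = {}
        mods.update({lm: "greater_utricle" for lm in utricle_singles})
        mods.update({c: "greater_utricle" for c in utricle_curves})
        mods.update({lm: "greater_saccule" for lm in saccule_singles})
        mods.update({c: "greater_saccule" for c in saccule_curves})
        return LandmarkSetDefinition(
            "6", utricle_singles + saccule_singles, utricle_curves + saccule_curves, mods
        )
    raise ValueError(f"unknown landmark set {set_id!r}")


# ---------------------------------------------------------------------------
# Procrustes machinery
# ---------------------------------------------------------------------------

def centroid_size(config: "LandmarkConfiguration | np.ndarray") -> float:
    """Centroid size: sqrt of summed squared distances of points from their centroid."""
    pts = config.points if isinstance(config, LandmarkConfiguration) else _as_points(config)
    if pts.shape[0] < 2:
        raise InvalidConfigurationError("centroid size needs at least 2 points")
    dev = pts - pts.mean(axis=0)
    return float(np.sqrt(np.sum(dev * dev)))


def _optimal_rotation(moving: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    """Proper rotation R (det = +1) minimizing ||moving @ R - fixed||_F.

    Both inputs must already be centered.  Reflections are excluded: mirrored
    (left vs right) labyrinths must be mirrored explicitly upstream.
    """
    H = moving.T @ fixed
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def opa_align(
    moving: LandmarkConfiguration,
    fixed: LandmarkConfiguration,
    allow_scale: bool = True,
) -> tuple[LandmarkConfiguration, float]:
    """Ordinary Procrustes superimposition of ``moving`` onto ``fixed``.

    Returns the transformed copy of ``moving`` (expressed in ``fixed``'s
    original frame) and the Procrustes distance: the root summed squared
    residual between the two configurations after centering, scaling each to
    unit centroid size and optimal rotation.  The distance is symmetric in
    its arguments.
    """
    if moving.k != fixed.k:
        raise InvalidConfigurationError(f"point counts differ: {moving.k} vs {fixed.k}")
    if moving.labels != fixed.labels:
        raise InvalidConfigurationError("landmark labels differ between configurations")
    M, F = moving.points, fixed.points
    Mc, Fc = M - M.mean(axis=0), F - F.mean(axis=0)
    cs_m, cs_f = np.sqrt((Mc ** 2).sum()), np.sqrt((Fc ** 2).sum())
    if cs_m <= 0 or cs_f <= 0:
        raise InvalidConfigurationError("zero-size configuration")
    Mu, Fu = Mc / cs_m, Fc / cs_f
    if min(np.linalg.matrix_rank(Mu), np.linalg.matrix_rank(Fu)) < 2:
        raise InvalidConfigurationError("configuration is rank-deficient (collinear points)")
    R = _optimal_rotation(Mu, Fu)
    dist = float(np.linalg.norm(Mu @ R - Fu))
    if allow_scale:
        # scale moving's size to best match fixed (in fixed's mm frame)
        beta = float(np.sum((Mc @ R) * Fc) / np.sum(Mc ** 2))
        transformed = beta * (Mc @ R) + F.mean(axis=0)
    else:
        transformed = Mc @ R + F.mean(axis=0)
    return moving.with_points(transformed), dist


def gpa(
    configs: list[LandmarkConfiguration],
    scale: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedShapeSet:
    """Generalized Procrustes superimposition of two or more configurations.

    Iteratively aligns every configuration to the current consensus until the
    change in the total Procrustes sum of squares falls below ``tol``.  With
    ``scale=True`` each configuration is scaled to unit centroid size
    (classical full-Procrustes convention); pre-scaling centroid sizes are
    recorded either way.
    """
    if len(configs) < 2:
        raise InvalidConfigurationError("GPA needs at least 2 configurations")
    labels = configs[0].labels
    for c in configs[1:]:
        if c.labels != labels:
            raise InvalidConfigurationError(
                f"configuration {c.specimen_id!r} has a different landmark scheme"
            )
    sizes = np.array([centroid_size(c) for c in configs])
    X = np.stack([c.points - c.points.mean(axis=0) for c in configs])
    if scale:
        X = X / sizes[:, None, None]

    # initial consensus: everything rotated onto the first configuration
    ref = X[0]
    for i in range(X.shape[0]):
        X[i] = X[i] @ _optimal_rotation(X[i], ref)
    consensus = X.mean(axis=0)

    ss_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(X.shape[0]):
            X[i] = X[i] @ _optimal_rotation(X[i], consensus)
        consensus = X.mean(axis=0)
        ss = float(np.sum((X - consensus[None]) ** 2))
        ss_trace.append(ss)
        if len(ss_trace) >= 2 and abs(ss_trace[-2] - ss) < tol:
            converged = True
            break

    c0 = configs[0]
    return AlignedShapeSet(
        coords=X,
        consensus=consensus,
        centroid_sizes=sizes,
        specimen_ids=[c.specimen_id for c in configs],
        labels=list(labels),
        roles=list(c0.roles),
        curve_ids=list(c0.curve_ids),
        blocks=list(c0.blocks),
        iterations=it,
        converged=converged,
        ss_trace=ss_trace,
    )


def subset_blocks(
    aligned: AlignedShapeSet, setdef: LandmarkSetDefinition
) -> dict[str, AlignedShapeSet]:
    """Split a jointly superimposed set into its module views.

    Returns one AlignedShapeSet view per module (e.g. bony / membranous)
    WITHOUT re-superimposition — the "within a configuration" approach, so
    the relative position and scale of the subsets is preserved exactly.
    """
    idx = setdef.point_indices(aligned.labels, aligned.curve_ids)
    views: dict[str, AlignedShapeSet] = {}
    module_names: list[str] = []
    for i in idx:
        m = setdef.module_of(aligned.labels[i], aligned.curve_ids[i])
        if m not in module_names:
            module_names.append(m)
    for m in module_names:
        sub = np.array(
            [i for i in idx
             if setdef.module_of(aligned.labels[i], aligned.curve_ids[i]) == m],
            dtype=int,
        )
        views[m] = aligned.take(sub)
    return views
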