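"""Plane fitting and maculae-orientation analysis.

The orientation of the utricular and saccular maculae is estimated two ways:
from triads of landmarks placed directly on each macula (LM17-19 utricular,
LM20-22 saccular) and from triads of bony landmarks surrounding each organ
(LM2/4/6 or LM2/4/5 for the utricle; LM8-10 or a selection of the
spherical-recess surface for the saccule).  The approximation angle between
the bony-derived and macula-derived planes, and the OLS regression of the
bony inter-macular angle on the true inter-macular angle, quantify how well
bone alone predicts maculae orientation.  All plane comparisons are computed
in the original (unsuperimposed) specimen frame, since orientation relative
to bone is the quantity of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landmarks import LandmarkConfiguration
from .statistics import OlsFit, ols_regress

__all__ = [
    "PlaneFit",
    "AngleComparison",
    "plane_from_triad",
    "plane_from_surface",
    "angle_between_planes",
    "maculae_orientation_analysis",
    "DEFAULT_PAIRINGS",
]


@dataclass
class PlaneFit:
    """A fitted plane: centroid point, unit normal and RMS residual (mm)."""

    point: np.ndarray
    normal: np.ndarray
    rms_residual: float
    source: str  # "triad" or "surface"


def plane_from_triad(p1, p2, p3) -> PlaneFit:
    """Exact plane through three non-collinear points."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    e1, e2 = p2 - p1, p3 - p1
    nvec = np.cross(e1, e2)
    norm = np.linalg.norm(nvec)
    scale = max(np.linalg.norm(e1), np.linalg.norm(e2), 1e-300)
    collinearity = norm / scale**2
    if collinearity < 1e-10:
        raise ValueError(f"collinear triad (normalized cross-product magnitude {collinearity:.3e})")
    return PlaneFit(
        point=(p1 + p2 + p3) / 3.0,
        normal=nvec / norm,
        rms_residual=0.0,
        source="triad",
    )


def plane_from_surface(points: np.ndarray) -> PlaneFit:
    """Total-least-squares plane through a point cloud (m >= 3, rank >= 2).

    The normal is the smallest principal direction of the centered points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("need an (m >= 3, 3) point cloud")
    centroid = pts.mean(axis=0)
    C = pts - centroid
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("rank-deficient point cloud (points are collinear)")
    normal = Vt[2]
    if normal[np.argmax(np.abs(normal))] < 0:  # deterministic sign
        normal = -normal
    resid = C @ normal
    return PlaneFit(
        point=centroid,
        normal=normal,
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        source="surface",
    )


def angle_between_planes(a: PlaneFit, b: PlaneFit) -> float:
    """Dihedral angle between two planes in degrees, folded to [0, 90]."""
    c = abs(float(np.dot(a.normal, b.normal)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class AngleComparison:
    specimen_id: str
    pairing: str
    bony_labels: tuple[str, ...]
    macular_source: str
    angle_deg: float


#: The eight bony-vs-macular plane pairings tested: four bony triad choices
#: for the utricular macula target (triad LM17-19 or the macular surface) and
#: four for the saccular macula target (triad LM20-22 or the surface).
DEFAULT_PAIRINGS: list[dict] = [
    {"name": "u_246_vs_triad", "bony": ("LM2", "LM4", "LM6"), "macula": "utricular", "target": "triad"},
    {"name": "u_245_vs_triad", "bony": ("LM2", "LM4", "LM5"), "macula": "utricular", "target": "triad"},
    {"name": "u_246_vs_surface", "bony": ("LM2", "LM4", "LM6"), "macula": "utricular", "target": "surface"},
    {"name": "u_245_vs_surface", "bony": ("LM2", "LM4", "LM5"), "macula": "utricular", "target": "surface"},
    {"name": "s_8910_vs_triad", "bony": ("LM8", "LM9", "LM10"), "macula": "saccular", "target": "triad"},
    {"name": "s_recess_vs_triad", "bony": "spherical_recess", "macula": "saccular", "target": "triad"},
    {"name": "s_8910_vs_surface", "bony": ("LM8", "LM9", "LM10"), "macula": "saccular", "target": "surface"},
    {"name": "s_recess_vs_surface", "bony": "spherical_recess", "macula": "saccular", "target": "surface"},
]

_MACULA_TRIADS = {"utricular": ("LM17", "LM18", "LM19"), "saccular": ("LM20", "LM21", "LM22")}


def _triad_plane(config: LandmarkConfiguration, labels: tuple[str, str, str]) -> PlaneFit:
    pts = [config.points[config.index_of(l)] for l in labels]
    return plane_from_triad(*pts)


def maculae_orientation_analysis(
    specimens: list[LandmarkConfiguration],
    macular_surfaces: dict[str, dict[str, np.ndarray]] | None = None,
    recess_selections: dict[str, np.ndarray] | None = None,
    pairings: list[dict] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, OlsFit]:
    """Bony-vs-macular plane comparison across specimens.

    Parameters
    ----------
    specimens
        Landmark configurations in their original (unsuperimposed) frames.
    macular_surfaces
        Optional per-specimen {"utricular": (m,3), "saccular": (m,3)} vertex
        clouds of the macular surfaces; needed for surface-target pairings.
    recess_selections
        Optional per-specimen (m,3) point selections of the spherical recess,
        a user-supplied region (no automatic detection).
    pairings
        Pairing specs (see DEFAULT_PAIRINGS).

    Returns
    -------
    (per-comparison table, per-pairing summary, inter-macular-angle OLS fit)

    The OLS fit regresses the bony inter-macular angle (between triads
    LM2/4/6 and LM8-10) on the true inter-macular angle (between triads
    LM17-19 and LM20-22) across specimens.
    """
    pairings = DEFAULT_PAIRINGS if pairings is None else pairings
    rows: list[AngleComparison] = []
    skipped: list[str] = []
    for config in specimens:
        sid = config.specimen_id
        for spec in pairings:
            try:
                if spec["bony"] == "spherical_recess":
                    if not recess_selections or sid not in recess_selections:
                        raise KeyError("no spherical-recess selection supplied")
                    bony_plane = plane_from_surface(recess_selections[sid])
                    bony_labels: tuple[str, ...] = ("spherical_recess",)
                else:
                    bony_plane = _triad_plane(config, spec["bony"])
                    bony_labels = tuple(spec["bony"])
                if spec["target"] == "triad":
                    mac_plane = _triad_plane(config, _MACULA_TRIADS[spec["macula"]])
                    source = f"{spec['macula']}_triad"
                else:
                    if not macular_surfaces or sid not in macular_surfaces:
                        raise KeyError("no macular surface supplied")
                    mac_plane = plane_from_surface(macular_surfaces[sid][spec["macula"]])
                    source = f"{spec['macula']}_surface"
                rows.append(
                    AngleComparison(
                        specimen_id=sid,
                        pairing=spec["name"],
                        bony_labels=bony_labels,
                        macular_source=source,
                        angle_deg=angle_between_planes(bony_plane, mac_plane),
                    )
                )
            except KeyError as exc:
                skipped.append(f"{sid}/{spec['name']}: {exc}")
    table = pd.DataFrame(
        [
            {
                "specimen_id": r.specimen_id,
                "pairing": r.pairing,
                "bony": "+".join(r.bony_labels),
                "macular_source": r.macular_source,
                "angle_deg": r.angle_deg,
            }
            for r in rows
        ]
    )
    if table.empty:
        raise ValueError(f"no comparisons computable; skipped: {skipped}")
    summary = (
        table.groupby("pairing")["angle_deg"]
        .agg(mean="mean", sd="std", min="min", max="max", n="count")
        .reset_index()
    )

    # inter-macular angle regression: bony-derived vs macula-derived
    bony_angles, true_angles = [], []
    for config in specimens:
        try:
            b_u = _triad_plane(config, ("LM2", "LM4", "LM6"))
            b_s = _triad_plane(config, ("LM8", "LM9", "LM10"))
            m_u = _triad_plane(config, _MACULA_TRIADS["utricular"])
            m_s = _triad_plane(config, _MACULA_TRIADS["saccular"])
        except KeyError:
            continue
        bony_angles.append(angle_between_planes(b_u, b_s))
        true_angles.append(angle_between_planes(m_u, m_s))
    fit = (
        ols_regress(np.asarray(true_angles), np.asarray(bony_angles))
        if len(true_angles) >= 3
        else None
    )
    return table, summary, fit
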