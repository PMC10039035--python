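"""Pipeline configuration and end-to-end orchestration.

Runs the analysis chain in study order on a directory of landmark files or a
synthetic population: GPA with semilandmark sliding; the PC1 and log
centroid-size OLS regression batteries; integration (2B-PLS) and modularity
(CR) tests over the six landmark sets; the maculae-orientation comparison;
SPHARM mean shapes; morphometric-model assembly; and reconstruction
validation.  Every run writes its resolved configuration and seeds next to
the outputs, and a run is bit-reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .assembly import assemble_model
from .landmarks import gpa, landmark_set, subset_blocks
from .planes import maculae_orientation_analysis
from .reconstruct import validate_reconstruction
from .spharm import DEFAULT_DEGREES, correspondence_align, pdm_sample, spharm_fit, spherical_parametrize
from .statistics import integration_for_set, regression_battery
from .synthetic import PopulationSpec, generate_population
from .tps import slide_semilandmarks

__all__ = [
    "PipelineConfig",
    "default_pc1_battery",
    "default_size_battery",
    "build_morphometric_model",
    "run_pipeline",
]


def _expand(singles: list[int] = (), curves: list[str] = ()) -> list[str]:
    from .landmarks import SEMILANDMARK_CURVES

    labels = [f"LM{i}" for i in singles]
    for c in curves:
        n = SEMILANDMARK_CURVES[c][0]
        labels += [f"{c}_{j + 1:02d}" for j in range(n)]
    return labels


# landmark shorthand for the battery layouts
_BONY_U_ALL = list(range(1, 7))
_BONY_U_246 = [2, 4, 6]
_BONY_U_245 = [2, 4, 5]
_BONY_S_ALL = [7, 8, 9, 10]
_BONY_S_TRIAD = [8, 9, 10]
_MEMB_U = [11, 12, 13]
_MAC_U = [17, 18, 19]
_MEMB_S = [14, 15, 16]
_MAC_S = [20, 21, 22]


def default_pc1_battery() -> list[tuple[str, list[str], list[str], str]]:
    """The eleven PC1 regressions: bony PC1 (response) on membranous PC1.

    Rows 1-5 use the six-set scheme's bony-vs-membranous splits (sets 1-5),
    row 6 the greater-utricle vs greater-saccule split (set 6), rows 7-10
    per-organ hard-vs-soft contrasts with and without semilandmark curves,
    and row 11 the whole bony block against the maculae alone.
    """
    rows = []
    for sid in ("1", "2", "3", "4", "5"):
        sd = landmark_set(sid)
        bony = [l for l in sd.included_singles if sd.modules[l] == "bony"]
        memb = [l for l in sd.included_singles if sd.modules[l] == "membranous"]
        bc = [c for c in sd.included_curves if sd.modules[c] == "bony"]
        mc = [c for c in sd.included_curves if sd.modules[c] == "membranous"]
        rows.append(
            (f"set{sid}",
             _expand([int(l[2:]) for l in bony], bc),
             _expand([int(l[2:]) for l in memb], mc),
             "pc1")
        )
    sd6 = landmark_set("6")
    gu = [l for l in sd6.included_singles if sd6.modules[l] == "greater_utricle"]
    gs = [l for l in sd6.included_singles if sd6.modules[l] == "greater_saccule"]
    rows.append(
        ("set6",
         _expand([int(l[2:]) for l in gu], ["SemiLM3", "SemiLM4"]),
         _expand([int(l[2:]) for l in gs], ["SemiLM1", "SemiLM2", "SemiLM5"]),
         "pc1")
    )
    rows += [
        ("utricle_semis", _expand(_BONY_U_ALL), _expand(_MEMB_U + _MAC_U, ["SemiLM3", "SemiLM4"]), "pc1"),
        ("utricle_singles", _expand(_BONY_U_ALL), _expand(_MEMB_U + _MAC_U), "pc1"),
        ("saccule_semis", _expand(_BONY_S_ALL, ["SemiLM1", "SemiLM2"]), _expand(_MEMB_S + _MAC_S, ["SemiLM5"]), "pc1"),
        ("saccule_singles", _expand(_BONY_S_ALL), _expand(_MEMB_S + _MAC_S), "pc1"),
        ("maculae_only", _expand(list(range(1, 11))), _expand(_MAC_U + _MAC_S), "pc1"),
    ]
    return rows


def default_size_battery() -> list[tuple[str, list[str], list[str], str]]:
    """The fifteen log centroid-size regressions (bony size on membranous size)."""
    layout = [
        ("size_u1", _BONY_U_ALL, _MEMB_U), ("size_u2", _BONY_U_ALL, _MAC_U),
        ("size_u3", _BONY_U_246, _MEMB_U), ("size_u4", _BONY_U_246, _MAC_U),
        ("size_u5", _BONY_U_245, _MEMB_U), ("size_u6", _BONY_U_245, _MAC_U),
        ("size_s1", _BONY_S_ALL, _MEMB_S), ("size_s2", _BONY_S_ALL, _MAC_S),
        ("size_s3", _BONY_S_TRIAD, _MEMB_S), ("size_s4", _BONY_S_TRIAD, _MAC_S),
        ("size_x1", _BONY_S_ALL, _MEMB_U), ("size_x2", _BONY_S_ALL, _MAC_U),
        ("size_x3", _BONY_U_ALL, _MEMB_S), ("size_x4", _BONY_U_ALL, _MAC_S),
        ("size_x5", _BONY_U_246, _MAC_S),
    ]
    return [(sid, _expand(b), _expand(m), "log_centroid_size") for sid, b, m in layout]


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run (fully serializable)."""

    seed: int = 0
    landmark_set_id: str = "1"
    scale: bool = True
    slide: bool = True
    n_permutations: int = 10_000
    spharm_degrees: dict = field(default_factory=lambda: dict(DEFAULT_DEGREES))
    spharm_subdivision: int = 15
    spharm_sample_size: int = 5
    voxel_size: float = 0.08
    reconstruction_sample_size: int = 5
    population: dict | None = None  # synthetic PopulationSpec overrides

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


def build_morphometric_model(specimens, aligned, config: PipelineConfig):
    """SPHARM mean shapes + consensus landmarks -> assembled morphometric model.

    The SPHARM sample (first ``config.spharm_sample_size`` specimens) is
    similarity-registered onto the first specimen's frame via the single
    landmarks (the landmark-based stand-in for pseudolandmark mesh
    alignment); each structure is parametrized, fitted at its per-structure
    degree and corresponded; the PDM mean meshes are then registered onto
    the consensus landmark configuration (expressed in mm via the mean
    centroid size) by fiducial similarity transforms.
    """
    from .assembly import fit_similarity
    from .spharm import mean_shape

    m = config.spharm_sample_size
    ref = specimens[0].config
    single_labels = [l for l, r in zip(ref.labels, ref.roles) if r == "single"]
    ref_pts = np.array([ref.points[ref.index_of(l)] for l in single_labels])
    reg_meshes: list[dict] = []
    reg_landmarks: list[dict] = []
    for s in specimens[:m]:
        src = np.array([s.config.points[s.config.index_of(l)] for l in single_labels])
        xf = fit_similarity(src, ref_pts)
        reg_meshes.append({k: xf.apply_mesh(mesh) for k, mesh in s.meshes.items()})
        reg_landmarks.append(dict(zip(single_labels, xf.apply(src))))
    models = {}
    for organ in ("vestibule", "utricle", "saccule"):
        degree = config.spharm_degrees.get(organ, 15)
        fits = []
        for rm in reg_meshes:
            mesh = rm[organ]
            param = spherical_parametrize(mesh)
            fits.append(spharm_fit(mesh, param, degree))
        models[organ] = correspondence_align(fits)

    consensus_cfg = aligned.consensus_configuration()
    # express the consensus in mm via the mean centroid size so mean meshes
    # and landmarks live on comparable scales
    consensus_mm = consensus_cfg.with_points(
        consensus_cfg.points * float(np.mean(aligned.centroid_sizes))
    )
    fid_labels_by_organ = {
        "vestibule": [f"LM{i}" for i in range(1, 11)],
        "utricle": ["LM11", "LM12", "LM13", "LM17", "LM18", "LM19"],
        "saccule": ["LM14", "LM15", "LM16", "LM20", "LM21", "LM22"],
    }
    mean_meshes = {}
    for organ in ("vestibule", "utricle", "saccule"):
        mm = mean_shape(models[organ], config.spharm_subdivision)
        # fiducials on the mean mesh: mean registered landmark positions
        fid = {
            lab: np.mean([rl[lab] for rl in reg_landmarks], axis=0)
            for lab in fid_labels_by_organ[organ]
        }
        mean_meshes[organ] = (mm, fid)
    return assemble_model(mean_meshes, consensus_mm, voxel_size=config.voxel_size)


def _file_checksums(outdir: Path) -> dict[str, str]:
    sums = {}
    for p in sorted(outdir.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            sums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return sums


def run_pipeline(
    config: PipelineConfig,
    outdir,
    data_dir=None,
    specimens=None,
) -> dict:
    """Execute the full analysis chain and write the report bundle.

    Inputs come from ``specimens`` (synthetic records), ``data_dir`` (a
    directory of landmark files; mesh-dependent stages are then skipped), or
    — when both are None — a synthetic population generated from
    ``config.population`` / ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    report: dict = {"config": asdict(config)}
    try:
        configs = None
        if specimens is None and data_dir is not None:
            paths = sorted(
                p for p in Path(data_dir).iterdir()
                if p.suffix in (".fcsv", ".csv") or p.name.endswith(".mrk.json")
            )
            configs = [lio.read_landmarks(p) for p in paths]
        if specimens is None and configs is None:
            pop_kwargs = dict(config.population or {})
            pop_kwargs.setdefault("seed", config.seed)
            specimens, _ = generate_population(PopulationSpec(**pop_kwargs))
        if configs is None:
            configs = [s.config for s in specimens]

        stage = "gpa"
        aligned = gpa(configs, scale=config.scale)
        if config.slide:
            stage = "slide"
            aligned = slide_semilandmarks(aligned)

        stage = "regression_battery"
        pc1_table = regression_battery(aligned, default_pc1_battery())
        size_table = regression_battery(aligned, default_size_battery())
        pc1_table.to_csv(outdir / "regression_pc1.csv", index=False)
        size_table.to_csv(outdir / "regression_size.csv", index=False)

        stage = "integration_modularity"
        rows = []
        for sid in ("1", "2", "3", "4", "5", "6"):
            integ, mod = integration_for_set(
                aligned, landmark_set(sid),
                n_perm=config.n_permutations, seed=config.seed + int(sid),
            )
            rows.append(
                {
                    "set_id": sid,
                    "r_pls": integ.r_pls, "p_integration": integ.p_value,
                    "z_integration": integ.effect_size_z,
                    "cr": mod.cr, "p_modularity": mod.p_value,
                    "z_modularity": mod.effect_size_z,
                    "n_perm": config.n_permutations, "seed": config.seed + int(sid),
                }
            )
        integration_table = pd.DataFrame(rows)
        integration_table.to_csv(outdir / "integration_modularity.csv", index=False)

        angles_table = summary = angle_fit = None
        if specimens is not None:
            stage = "maculae_angles"
            angles_table, summary, angle_fit = maculae_orientation_analysis(
                [s.config for s in specimens],
                macular_surfaces={s.specimen_id: s.macular_surfaces for s in specimens},
                recess_selections={s.specimen_id: s.recess_selection for s in specimens},
            )
            angles_table.to_csv(outdir / "maculae_angles.csv", index=False)
            summary.to_csv(outdir / "maculae_angles_summary.csv", index=False)

            stage = "spharm+assemble"
            model = build_morphometric_model(specimens, aligned, config)

            stage = "reconstruct"
            r = config.reconstruction_sample_size
            recon_specs = [
                {
                    "specimen_id": s.specimen_id,
                    "config": s.config,
                    "utricle": s.meshes["utricle"],
                    "saccule": s.meshes["saccule"],
                }
                for s in specimens[:r]
            ]
            _, recon_table, comparison = validate_reconstruction(model, recon_specs)
            recon_table.to_csv(outdir / "reconstruction.csv", index=False)
            (outdir / "reconstruction_comparison.json").write_text(
                json.dumps(comparison, indent=2, sort_keys=True)
            )

        stage = "report"
        report.update(
            {
                "n_specimens": aligned.n,
                "gpa_iterations": aligned.iterations,
                "gpa_converged": bool(aligned.converged),
                "pc1_rows": int(len(pc1_table)),
                "size_rows": int(len(size_table)),
            }
        )
        if angle_fit is not None:
            report["angle_regression_r2"] = angle_fit.r_squared
            report["angle_regression_p"] = angle_fit.p_value
        (outdir / "manifest.json").write_text(
            json.dumps(
                {"config": asdict(config), "report": report, "checksums": _file_checksums(outdir)},
                indent=2, sort_keys=True, default=str,
            )
        )
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
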