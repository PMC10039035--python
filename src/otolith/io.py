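"""Landmark file I/O: 3D Slicer .fcsv and .mrk.json, plain CSV, classic TPS.

Coordinates are stored in RAS, millimetres, right-handed.  Slicer files
declare their coordinate system in a header/field; LPS files are converted to
RAS on read (sign flip on x and y).  Labels follow the LM1-LM22 /
SemiLM1-SemiLM5 scheme; a label like ``SemiLM3_04`` marks the fourth point of
curve SemiLM3.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path

import numpy as np

from .landmarks import (
    LandmarkConfiguration,
    SEMILANDMARK_CURVES,
    SINGLE_LANDMARKS,
)

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_fcsv",
    "write_fcsv",
    "read_mrk_json",
    "write_mrk_json",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_tps",
    "write_tps",
]

_CURVE_LABEL = re.compile(r"^(SemiLM\d+)_(\d+)$")


def _metadata_for(label: str) -> tuple[str, str | None, str]:
    """(role, curve_id, block) from a normalized label."""
    m = _CURVE_LABEL.match(label)
    if m:
        cid = m.group(1)
        if cid not in SEMILANDMARK_CURVES:
            raise ValueError(f"unknown semilandmark curve in label {label!r}")
        return "semilandmark", cid, SEMILANDMARK_CURVES[cid][1]
    if label in SINGLE_LANDMARKS:
        return "single", None, SINGLE_LANDMARKS[label]
    raise ValueError(f"unknown landmark label {label!r}")


def _build_config(specimen_id: str, rows: list[tuple[str, float, float, float]]) -> LandmarkConfiguration:
    labels, pts, roles, curves, blocks = [], [], [], [], []
    unknown = []
    for label, x, y, z in rows:
        try:
            role, cid, block = _metadata_for(label)
        except ValueError:
            unknown.append(label)
            continue
        labels.append(label)
        pts.append((x, y, z))
        roles.append(role)
        curves.append(cid)
        blocks.append(block)
    if unknown:
        raise ValueError(f"unknown landmark labels: {unknown}")
    return LandmarkConfiguration(
        specimen_id=specimen_id,
        points=np.asarray(pts, dtype=float),
        labels=labels,
        roles=roles,
        curve_ids=curves,
        blocks=blocks,
    )


# ---------------------------------------------------------------------------
# Slicer .fcsv
# ---------------------------------------------------------------------------

def read_fcsv(path) -> LandmarkConfiguration:
    path = Path(path)
    coordinate_system = "RAS"
    rows: list[tuple[str, float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.search(r"CoordinateSystem\s*=\s*(\w+)", line)
                if m:
                    coordinate_system = m.group(1).upper()
                    if coordinate_system == "0":
                        coordinate_system = "RAS"
                    elif coordinate_system == "1":
                        coordinate_system = "LPS"
                continue
            parts = line.split(",")
            if len(parts) < 12:
                raise ValueError(f"{path.name}:{lineno}: malformed fcsv row ({len(parts)} columns)")
            try:
                x, y, z = float(parts[1]), float(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: non-numeric coordinates") from exc
            label = parts[11].strip()
            if coordinate_system == "LPS":
                x, y = -x, -y
            rows.append((label, x, y, z))
    return _build_config(path.stem, rows)


def write_fcsv(path, config: LandmarkConfiguration) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# Markups fiducial file version = 4.11\n")
        fh.write("# CoordinateSystem = RAS\n")
        fh.write("# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n")
        for i, (label, p) in enumerate(zip(config.labels, config.points), start=1):
            fh.write(
                f"vtkMRMLMarkupsFiducialNode_{i},{p[0]:.9f},{p[1]:.9f},{p[2]:.9f},"
                f"0,0,0,1,1,1,0,{label},,\n"
            )


# ---------------------------------------------------------------------------
# Slicer .mrk.json
# ---------------------------------------------------------------------------

def read_mrk_json(path) -> LandmarkConfiguration:
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    rows = []
    for markup in doc.get("markups", []):
        cs = markup.get("coordinateSystem", "RAS").upper()
        for cp in markup.get("controlPoints", []):
            x, y, z = (float(v) for v in cp["position"])
            if cs == "LPS":
                x, y = -x, -y
            rows.append((cp["label"], x, y, z))
    if not rows:
        raise ValueError(f"{path.name}: no control points found")
    name = path.name
    for suffix in (".mrk.json", ".json"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    return _build_config(name, rows)


def write_mrk_json(path, config: LandmarkConfiguration) -> None:
    doc = {
        "@schema": "https://raw.githubusercontent.com/slicer/slicer/master/Modules/Loadable/Markups/Resources/Schema/markups-schema-v1.0.3.json",
        "markups": [
            {
                "type": "Fiducial",
                "coordinateSystem": "RAS",
                "controlPoints": [
                    {
                        "id": str(i + 1),
                        "label": label,
                        "position": [float(p[0]), float(p[1]), float(p[2])],
                    }
                    for i, (label, p) in enumerate(zip(config.labels, config.points))
                ],
            }
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# plain CSV
# ---------------------------------------------------------------------------

_CSV_FIELDS = ["specimen", "label", "role", "curve", "block", "x", "y", "z"]


def read_landmarks_csv(path) -> LandmarkConfiguration:
    path = Path(path)
    rows = []
    specimen = path.stem
    with open(path) as fh:
        reader = csv.DictReader(fh)
        missing = [f for f in _CSV_FIELDS if f not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"{path.name}: missing CSV columns {missing}")
        for lineno, rec in enumerate(reader, start=2):
            try:
                rows.append((rec["label"], float(rec["x"]), float(rec["y"]), float(rec["z"])))
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path.name}:{lineno}: malformed row") from exc
            specimen = rec["specimen"] or specimen
    return _build_config(specimen, rows)


def write_landmarks_csv(path, config: LandmarkConfiguration) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS)
        for label, role, cid, block, p in zip(
            config.labels, config.roles, config.curve_ids, config.blocks, config.points
        ):
            writer.writerow(
                [config.specimen_id, label, role, cid or "", block,
                 f"{p[0]:.9f}", f"{p[1]:.9f}", f"{p[2]:.9f}"]
            )


# ---------------------------------------------------------------------------
# classic TPS text (multi-specimen)
# ---------------------------------------------------------------------------

def read_tps(path, template: LandmarkConfiguration | None = None) -> list[LandmarkConfiguration]:
    """Read a classic TPS file (LM3= blocks) into configurations.

    TPS files carry no labels, so point order must follow the full scheme
    (or the supplied template's labels/roles/curves).
    """
    path = Path(path)
    from .landmarks import full_scheme_template

    if template is not None:
        labels, roles, curves, blocks = (
            list(template.labels), list(template.roles),
            list(template.curve_ids), list(template.blocks),
        )
    else:
        labels, roles, curves, blocks = full_scheme_template()
    configs = []
    pts: list[list[float]] = []
    spec_id = None
    expecting = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            m = re.match(r"^LM3?\s*=\s*(\d+)$", line, flags=re.I)
            if m:
                expecting = int(m.group(1))
                pts = []
                spec_id = None
                continue
            if line.upper().startswith("ID="):
                spec_id = line.split("=", 1)[1].strip()
                if len(pts) != expecting:
                    raise ValueError(f"{path.name}:{lineno}: expected {expecting} points, got {len(pts)}")
                configs.append(
                    LandmarkConfiguration(
                        specimen_id=spec_id or f"specimen{len(configs) + 1}",
                        points=np.asarray(pts, dtype=float),
                        labels=labels[: len(pts)],
                        roles=roles[: len(pts)],
                        curve_ids=curves[: len(pts)],
                        blocks=blocks[: len(pts)],
                    )
                )
                continue
            vals = line.split()
            if len(vals) != 3:
                raise ValueError(f"{path.name}:{lineno}: expected 3 coordinates")
            pts.append([float(v) for v in vals])
    return configs


def write_tps(path, configs: list[LandmarkConfiguration]) -> None:
    with open(path, "w") as fh:
        for cfg in configs:
            fh.write(f"LM3={cfg.k}\n")
            for p in cfg.points:
                fh.write(f"{p[0]:.9f} {p[1]:.9f} {p[2]:.9f}\n")
            fh.write(f"ID={cfg.specimen_id}\n")


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_READERS = {
    "fcsv": read_fcsv,
    "mrk.json": read_mrk_json,
    "csv": read_landmarks_csv,
}


def read_landmarks(path, fmt: str | None = None) -> LandmarkConfiguration:
    """Read one specimen's landmarks, inferring the format from the suffix."""
    path = Path(path)
    if fmt is None:
        name = path.name.lower()
        if name.endswith(".mrk.json"):
            fmt = "mrk.json"
        elif name.endswith(".fcsv"):
            fmt = "fcsv"
        elif name.endswith(".csv"):
            fmt = "csv"
        elif name.endswith(".tps"):
            raise ValueError("TPS files hold multiple specimens; use read_tps()")
        else:
            raise ValueError(f"cannot infer landmark format from {path.name!r}")
    if fmt not in _READERS:
        raise ValueError(f"unknown landmark format {fmt!r}")
    return _READERS[fmt](path)


def write_landmarks(path, config: LandmarkConfiguration, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        name = path.name.lower()
        fmt = "mrk.json" if name.endswith(".mrk.json") else (
            "fcsv" if name.endswith(".fcsv") else "csv"
        )
    {"fcsv": write_fcsv, "mrk.json": write_mrk_json, "csv": write_landmarks_csv}[fmt](path, config)
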