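"""Readers and writers for every external representation.

Formats:

* surfaces — PLY (via trimesh) or VTK legacy ASCII polydata (own
  reader/writer, including named per-vertex scalar channels and region
  flags); only triangular cells are accepted.
* SI volumes — NIfTI (.nii / .nii.gz) via nibabel.
* electroanatomic maps — plain CSV with ``#``-prefixed metadata lines
  (``# cl_ms=<float>``) and columns ``egm_id,x_mm,y_mm,z_mm,time_ms,tag``.
* landmarks — JSON object with the four required landmark names.

All loaders validate structural invariants and never reorder vertices or
EGM records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .core import SIVolume, TriSurface, ValidationError

EGM_TAGS = (
    "activation",
    "entrainment_isthmus",
    "pacemap_entrance",
    "pacemap_exit",
    "ablation_lesion",
)


@dataclass
class EGMRecord:
    """One mapping point: 3D position (mm), optional activation time, tag."""

    egm_id: int
    position: np.ndarray
    time_ms: float | None
    tag: str

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64).reshape(3)
        if self.tag not in EGM_TAGS:
            raise ValidationError(f"unknown EGM tag {self.tag!r}")
        if (self.tag == "activation") != (self.time_ms is not None):
            raise ValidationError(
                f"EGM {self.egm_id}: time_ms must be present iff tag is 'activation'"
            )


@dataclass
class ActivationMap:
    """EGM points of one VT morphology plus its cycle length."""

    egms: list
    cl_ms: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [e.egm_id for e in self.egms]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate EGM ids")

    def positions(self) -> np.ndarray:
        return np.asarray([e.position for e in self.egms])

    def times(self) -> np.ndarray:
        return np.asarray(
            [e.time_ms if e.time_ms is not None else np.nan for e in self.egms]
        )


# ------------------------------------------------------------------ surfaces
def write_surface(surface: TriSurface, path) -> None:
    path = Path(path)
    if path.suffix == ".ply":
        _write_ply(surface, path)
    elif path.suffix == ".vtk":
        _write_vtk(surface, path)
    else:
        raise ValidationError(f"unsupported surface format {path.suffix!r}")


def read_surface(path) -> TriSurface:
    path = Path(path)
    if path.suffix == ".ply":
        surf = _read_ply(path)
    elif path.suffix == ".vtk":
        surf = _read_vtk(path)
    else:
        raise ValidationError(f"unsupported surface format {path.suffix!r}")
    surf.validate()
    return surf


def _write_ply(surface: TriSurface, path: Path) -> None:
    mesh = trimesh.Trimesh(
        vertices=surface.vertices, faces=surface.faces, process=False
    )
    path.write_bytes(mesh.export(file_type="ply", encoding="ascii"))
    extras = _sidecar_dict(surface)
    if extras:
        path.with_suffix(".ply.json").write_text(json.dumps(extras, sort_keys=True))


def _read_ply(path: Path) -> TriSurface:
    mesh = trimesh.load(path, file_type="ply", process=False)
    surf = TriSurface(np.asarray(mesh.vertices), np.asarray(mesh.faces))
    side = path.with_suffix(".ply.json")
    if side.exists():
        _load_sidecar(surf, json.loads(side.read_text()))
    return surf


def _sidecar_dict(surface: TriSurface) -> dict:
    out = {}
    if surface.scalar_channels:
        out["scalar_channels"] = {
            k: np.asarray(v, dtype=float).tolist()
            for k, v in sorted(surface.scalar_channels.items())
        }
    if surface.region_flags:
        out["region_flags"] = {
            k: np.asarray(v, dtype=bool).astype(int).tolist()
            for k, v in sorted(surface.region_flags.items())
        }
    return out


def _load_sidecar(surf: TriSurface, extras: dict) -> None:
    for k, v in extras.get("scalar_channels", {}).items():
        surf.scalar_channels[k] = np.asarray(v, dtype=np.float64)
    for k, v in extras.get("region_flags", {}).items():
        surf.region_flags[k] = np.asarray(v, dtype=bool)


def _write_vtk(surface: TriSurface, path: Path) -> None:
    n, m = surface.n_vertices, surface.n_faces
    lines = [
        "# vtk DataFile Version 3.0",
        "vtcorridor surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    for v in surface.vertices:
        lines.append(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}")
    lines.append(f"POLYGONS {m} {4 * m}")
    for f in surface.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    channels = dict(sorted(surface.scalar_channels.items()))
    for name, flags in sorted(surface.region_flags.items()):
        channels[f"flag_{name}"] = np.asarray(flags, dtype=float)
    if channels:
        lines.append(f"POINT_DATA {n}")
        for name, values in channels.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(repr(float(x)) for x in np.asarray(values, dtype=float))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_vtk(path: Path) -> TriSurface:
    tokens = Path(path).read_text().splitlines()
    it = iter(range(len(tokens)))
    idx = 0

    def line() -> str:
        nonlocal idx
        while idx < len(tokens) and not tokens[idx].strip():
            idx += 1
        out = tokens[idx]
        idx += 1
        return out

    header = [line() for _ in range(4)]
    if "POLYDATA" not in header[3]:
        raise ValidationError("not a VTK polydata file")
    pts_hdr = line().split()
    n = int(pts_hdr[1])
    vertices = np.asarray([[float(x) for x in line().split()] for _ in range(n)])
    poly_hdr = line().split()
    m = int(poly_hdr[1])
    faces = []
    for ci in range(m):
        row = [int(x) for x in line().split()]
        if row[0] != 3:
            raise ValidationError(f"non-triangular cell at index {ci} ({row[0]} vertices)")
        faces.append(row[1:4])
    surf = TriSurface(vertices, np.asarray(faces, dtype=np.int64))
    # optional POINT_DATA scalars
    while idx < len(tokens):
        row = line().split() if idx < len(tokens) else []
        if not row:
            break
        if row[0] == "POINT_DATA":
            continue
        if row[0] == "SCALARS":
            name = row[1]
            line()  # LOOKUP_TABLE
            vals = np.asarray([float(line()) for _ in range(n)])
            if name.startswith("flag_"):
                surf.region_flags[name[5:]] = vals > 0.5
            else:
                surf.scalar_channels[name] = vals
    return surf


# ------------------------------------------------------------------- volumes
def write_volume(vol: SIVolume, path) -> None:
    img = nib.Nifti1Image(vol.array.astype(np.float32), vol.affine)
    nib.save(img, str(path))


def read_volume(path) -> SIVolume:
    img = nib.load(str(path))
    vol = SIVolume(np.asarray(img.get_fdata(), dtype=np.float64), img.affine)
    vol.validate()
    return vol


# ------------------------------------------------------------------ EGM maps
def write_egm_map(amap: ActivationMap, path) -> None:
    lines = []
    if amap.cl_ms is not None:
        lines.append(f"# cl_ms={amap.cl_ms:.9g}")
    for k, v in sorted(amap.meta.items()):
        lines.append(f"# {k}={v}")
    lines.append("egm_id,x_mm,y_mm,z_mm,time_ms,tag")
    for e in amap.egms:
        t = "" if e.time_ms is None else f"{e.time_ms:.9g}"
        p = e.position
        lines.append(f"{e.egm_id},{p[0]:.9g},{p[1]:.9g},{p[2]:.9g},{t},{e.tag}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_egm_map(path) -> ActivationMap:
    text = Path(path).read_text().splitlines()
    meta: dict = {}
    body = []
    for row in text:
        if row.startswith("#"):
            k, _, v = row.lstrip("# ").partition("=")
            meta[k.strip()] = v.strip()
        elif row.strip():
            body.append(row)
    df = pd.read_csv(pd.io.common.StringIO("\n".join(body)), dtype={"tag": str})
    required = {"egm_id", "x_mm", "y_mm", "z_mm", "time_ms", "tag"}
    if not required.issubset(df.columns):
        raise ValidationError(f"EGM CSV missing columns {sorted(required - set(df.columns))}")
    cl_ms = float(meta.pop("cl_ms")) if "cl_ms" in meta else None
    egms = []
    for _, row in df.iterrows():
        time = None if pd.isna(row["time_ms"]) else float(row["time_ms"])
        egms.append(
            EGMRecord(
                egm_id=int(row["egm_id"]),
                position=np.asarray([row["x_mm"], row["y_mm"], row["z_mm"]]),
                time_ms=time,
                tag=str(row["tag"]),
            )
        )
    if any(e.tag == "activation" for e in egms) and cl_ms is None:
        raise ValidationError("activation map without '# cl_ms=' header")
    return ActivationMap(egms=egms, cl_ms=cl_ms, meta=meta)


# ----------------------------------------------------------------- landmarks
def write_landmarks(landmarks, path) -> None:
    out = {k: np.asarray(v, dtype=float).tolist() for k, v in landmarks.points.items()}
    Path(path).write_text(json.dumps(out, sort_keys=True, indent=1))


def read_landmarks(path):
    from .ep_roi import LandmarkSet

    data = json.loads(Path(path).read_text())
    return LandmarkSet({k: np.asarray(v, dtype=np.float64) for k, v in data.items()})
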