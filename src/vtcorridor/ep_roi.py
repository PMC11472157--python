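"""EP-defined VT regions of interest and registration onto the CMR geometry.

The VT ROI is delineated from mapping data of one VT morphology.  For
activation maps the selection window runs from the latest activation point
back 35% of the cycle length and from the earliest activation point
forward 10% of the cycle length (times in ms relative to QRS onset, no
modular wrapping), plus the junction between the earliest and latest
points.  Point sets become surface regions through geodesic discs of
configurable radius (default 5 mm) — mapping data carries no intrinsic
lateral extent, so the radius is an explicit, reported parameter.

Registration between the electroanatomic and CMR geometries is a
least-squares landmark fit (Kabsch/Umeyama, via scikit-image) on four
anatomical landmarks: aortic root, LV apex, and the septal and lateral
mitral annulus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage.transform import EuclideanTransform, SimilarityTransform

from .core import (
    RigidTransform,
    TriSurface,
    ValidationError,
    connected_vertex_components,
    geodesic_distances,
    geodesic_path,
)
from .io_formats import ActivationMap

LANDMARK_NAMES = ("aortic_root", "lv_apex", "mitral_septal", "mitral_lateral")

ROI_MODES = ("activation", "entrainment", "pacemap")


@dataclass
class LandmarkSet:
    """The four named registration landmarks (mm)."""

    points: dict

    def __post_init__(self) -> None:
        if set(self.points) != set(LANDMARK_NAMES):
            raise ValidationError(
                f"landmark names must be exactly {LANDMARK_NAMES}, got {sorted(self.points)}"
            )
        self.points = {k: np.asarray(self.points[k], dtype=np.float64).reshape(3) for k in LANDMARK_NAMES}

    def as_array(self) -> np.ndarray:
        return np.asarray([self.points[k] for k in LANDMARK_NAMES])


@dataclass
class VTROI:
    """EP-defined VT region of interest on the CMR base mesh."""

    vertex_ids: np.ndarray
    mode: str
    area_cm2: float
    egm_roles: dict = field(default_factory=dict)  # egm_id -> {isthmus, curvature, other}
    radius_mm: float = 5.0


# ------------------------------------------------------------- window rule
def select_roi_egms(amap: ActivationMap) -> np.ndarray:
    """Boolean window membership per EGM under the -35% / +10% CL rule.

    An activation EGM is selected iff its time is within 0.35*CL of the
    latest activation point or within 0.10*CL after the earliest one.
    Non-activation EGMs are never selected.
    """
    if amap.cl_ms is None:
        raise ValidationError("activation map has no cycle length")
    times = amap.times()
    act = ~np.isnan(times)
    if not act.any():
        raise ValidationError("no activation points in map")
    t_late = np.nanmax(times)
    t_early = np.nanmin(times)
    win = np.zeros(len(times), dtype=bool)
    win[act] = (times[act] >= t_late - 0.35 * amap.cl_ms) | (
        times[act] <= t_early + 0.10 * amap.cl_ms
    )
    return win


# ----------------------------------------------------------- registration
def fit_landmark_transform(
    source: LandmarkSet, target: LandmarkSet, allow_scale: bool = False
) -> tuple:
    """Least-squares landmark transform source -> target.

    Rigid by default; ``allow_scale`` adds an isotropic scale (similarity).
    Returns ``(RigidTransform, residual_rms_mm)``.
    """
    src = source.as_array()
    dst = target.as_array()
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-6 * max(1.0, np.abs(centered).max())) < 2:
        raise ValidationError("landmarks are collinear; transform is degenerate")
    cls = SimilarityTransform if allow_scale else EuclideanTransform
    if hasattr(cls, "from_estimate"):
        tf = cls.from_estimate(src, dst)
        if not tf:
            raise ValidationError("landmark transform estimation failed")
    else:  # older scikit-image
        tf = cls(dimensionality=3)
        if not tf.estimate(src, dst):
            raise ValidationError("landmark transform estimation failed")
    m = np.asarray(tf.params)
    scale = float(np.cbrt(np.linalg.det(m[:3, :3]))) if allow_scale else 1.0
    rot = m[:3, :3] / scale
    out = RigidTransform(rot, m[:3, 3], scale)
    out.validate(tol=1e-6)
    res = out.apply(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return out, rms


def transfer_egms(
    amap: ActivationMap,
    transform: RigidTransform,
    base: TriSurface,
    max_distance_mm: float = 10.0,
) -> dict:
    """Map each EGM to its nearest base-mesh vertex after transforming.

    Returns ``egm_id -> (vertex_id, distance_mm)``; EGMs farther than
    ``max_distance_mm`` from the surface are flagged unmapped (vertex -1)
    and excluded downstream, with a warning.
    """
    pts = transform.apply(amap.positions())
    tree = cKDTree(base.vertices)
    dist, vid = tree.query(pts)
    out = {}
    n_unmapped = 0
    for e, d, v in zip(amap.egms, dist, vid):
        if d > max_distance_mm:
            out[e.egm_id] = (-1, float(d))
            n_unmapped += 1
        else:
            out[e.egm_id] = (int(v), float(d))
    if n_unmapped:
        warnings.warn(f"{n_unmapped} EGMs farther than {max_distance_mm} mm from the surface; excluded")
    return out


# -------------------------------------------------------------------- ROI
def _disc_union(base: TriSurface, seeds: np.ndarray, radius_mm: float) -> np.ndarray:
    d = geodesic_distances(base, seeds, limit=radius_mm * 1.001)
    return np.flatnonzero(d <= radius_mm)


def build_roi(
    amap: ActivationMap,
    mode: str,
    base: TriSurface,
    assignments: dict,
    radius_mm: float = 5.0,
    egm_roles: dict | None = None,
) -> VTROI:
    """Build the VT ROI on the CMR base mesh.

    activation — geodesic discs around window EGMs plus discs along the
    geodesic junction from the earliest to the latest activation point;
    pacemap — discs around entrance and exit sites plus the connecting
    geodesic path; entrainment — discs around the isthmus points plus a
    chain of connecting paths.
    """
    if mode not in ROI_MODES:
        raise ValidationError(f"unknown ROI mode {mode!r}")
    mapped = {eid: v for eid, (v, _) in assignments.items() if v >= 0}

    def vertices_for(egms) -> np.ndarray:
        return np.asarray(sorted({mapped[e.egm_id] for e in egms if e.egm_id in mapped}), dtype=np.int64)

    seeds_list: list = []
    path_pairs: list = []
    if mode == "activation":
        win = select_roi_egms(amap)
        window_egms = [e for e, w in zip(amap.egms, win) if w]
        seeds = vertices_for(window_egms)
        if seeds.size == 0:
            raise ValidationError("no mapped EGMs inside the ROI window")
        times = amap.times()
        act_ids = [e.egm_id for e in amap.egms if e.time_ms is not None and e.egm_id in mapped]
        act_t = {e.egm_id: e.time_ms for e in amap.egms if e.time_ms is not None}
        earliest = min(act_ids, key=lambda i: act_t[i])
        latest = max(act_ids, key=lambda i: act_t[i])
        seeds_list.append(seeds)
        path_pairs.append((mapped[earliest], mapped[latest]))
    elif mode == "pacemap":
        entr = [e for e in amap.egms if e.tag == "pacemap_entrance"]
        exit_ = [e for e in amap.egms if e.tag == "pacemap_exit"]
        if not entr or not exit_:
            raise ValidationError("pacemap mode needs entrance and exit points")
        v_in, v_out = vertices_for(entr), vertices_for(exit_)
        seeds_list.extend([v_in, v_out])
        path_pairs.append((int(v_in[0]), int(v_out[0])))
    else:  # entrainment
        pts = [e for e in amap.egms if e.tag == "entrainment_isthmus"]
        if len(pts) < 2:
            raise ValidationError("entrainment mode needs >= 2 isthmus points")
        vs = [mapped[e.egm_id] for e in pts if e.egm_id in mapped]
        seeds_list.append(np.asarray(sorted(set(vs)), dtype=np.int64))
        path_pairs.extend(zip(vs[:-1], vs[1:]))

    member: set = set()
    for seeds in seeds_list:
        member.update(_disc_union(base, seeds, radius_mm).tolist())
    for v0, v1 in path_pairs:
        if v0 == v1:
            continue
        path = geodesic_path(base, v0, v1)
        member.update(_disc_union(base, path, radius_mm).tolist())

    vertex_ids = np.asarray(sorted(member), dtype=np.int64)
    roi = VTROI(
        vertex_ids=vertex_ids,
        mode=mode,
        area_cm2=base.area_cm2(vertex_ids),
        egm_roles=dict(egm_roles or {}),
        radius_mm=radius_mm,
    )
    comps = connected_vertex_components(
        base.vertex_adjacency(), np.isin(np.arange(base.n_vertices), vertex_ids)
    )
    if len(comps) > 1:
        warnings.warn(f"ROI has {len(comps)} components after junction construction")
    return roi
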