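"""Synthetic left-ventricular phantom with ground-truthed scar anatomy.

The LV is modelled as a truncated ellipsoidal shell: the endocardium is an
ellipsoid with semi-axes ``endo_radii`` cut by a basal plane (stand-in for
the mitral annulus), and the epicardium is the outward offset of that
surface by ``wall_thickness`` along the endocardial normal.  Because the
offset of a convex surface preserves the normal distance, the transmural
coordinate of any point in the wall is exactly its Euclidean distance to
the endocardial ellipsoid divided by the wall thickness — which gives
closed-form ground truth for every downstream stage.

A dense-core scar patch is an angular window of the shell; border-zone
conducting channels are meridian strips of controlled signal intensity and
transmural depth carved through the core.  Decoy channels share the
geometry but are flagged non-functional: no reentrant circuit runs through
them.  Signal intensity is generated directly on the percent-of-maximum
scale (dense core = 100), so cut-off semantics downstream need no separate
calibration.  Cavity and background voxels take the remote-myocardium
level: in late-enhancement imaging the blood pool is not dark, and a zero
background would create an artificial dark rim under trilinear sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import RigidTransform, SIVolume, TriSurface, ValidationError, geodesic_distances
from .ep_roi import LandmarkSet, LANDMARK_NAMES
from .io_formats import ActivationMap, EGMRecord

__all__ = [
    "ScarPatchSpec",
    "ChannelSpec",
    "PhantomSpec",
    "GroundTruth",
    "make_lv_phantom",
    "make_synthetic_vt_map",
    "ellipsoid_foot_points",
]


# --------------------------------------------------------------------- specs
@dataclass
class ScarPatchSpec:
    """Angular window of dense-core scar on the shell.

    ``theta_deg`` is the longitude window (degrees, -180..180), ``u_deg``
    the polar-angle window measured from the apex (0 = apex), and
    ``depth`` the transmural fraction span the core occupies.
    """

    theta_deg: tuple = (-70.0, 70.0)
    u_deg: tuple = (50.0, 115.0)
    depth: tuple = (0.0, 1.0)


@dataclass
class ChannelSpec:
    """Border-zone strip along a meridian of the mid-wall.

    The strip is centred on longitude ``theta_deg``, spans the polar range
    ``u_deg`` and has metric half-width ``width_mm / 2`` measured along the
    local circumference.  ``si_pct`` is its signal intensity in percent of
    the dense-core maximum; ``depth_span`` the transmural fractions it
    occupies.  Non-functional channels are decoys: anatomically identical
    border-zone strips that no reentrant circuit uses.
    """

    theta_deg: float = -35.0
    u_deg: tuple = (45.0, 118.0)
    width_mm: float = 8.0
    si_pct: float = 43.0
    depth_span: tuple = (0.1, 0.5)
    functional: bool = True


@dataclass
class PhantomSpec:
    """Full description of a synthetic LV phantom (deterministic per seed)."""

    endo_radii: tuple = (22.0, 22.0, 40.0)
    wall_thickness: float = 10.0
    voxel_size: float = 1.5
    base_fraction: float = 0.5  # basal plane at z = base_fraction * c
    healthy_si: float = 15.0
    core_si: float = 100.0
    scar_patch: ScarPatchSpec | None = field(default_factory=ScarPatchSpec)
    channels: list = field(default_factory=lambda: [ChannelSpec()])
    decoys: list = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0
    mesh_edge_mm: float = 2.0

    def validate(self) -> None:
        a, b, c = self.endo_radii
        if min(a, b, c) <= 0:
            raise ValidationError("endo radii must be positive")
        if self.wall_thickness <= 2 * self.voxel_size:
            raise ValidationError(
                "wall thinner than 2 voxels: "
                f"{self.wall_thickness} mm vs voxel {self.voxel_size} mm"
            )
        if not (0.0 < self.base_fraction < 1.0):
            raise ValidationError("base_fraction must be in (0, 1)")
        u_max = math.degrees(math.acos(-self.base_fraction))
        patch = self.scar_patch
        if patch is None:
            if self.channels or self.decoys:
                raise ValidationError("channels require a scar patch to run through")
            patch_arc = math.inf
        else:
            if not (0 <= patch.u_deg[0] < patch.u_deg[1] <= u_max + 5):
                raise ValidationError("scar patch polar span outside shell parameterization")
            patch_arc = math.radians(patch.theta_deg[1] - patch.theta_deg[0]) * 0.5 * (a + b)
        for ch in list(self.channels) + list(self.decoys):
            lo, hi = ch.depth_span
            if not (0.0 <= lo < hi <= 1.0):
                raise ValidationError("channel depth_span must be within [0, 1]")
            if ch.width_mm <= 0:
                raise ValidationError("channel width must be positive")
            if ch.width_mm >= patch_arc:
                raise ValidationError(
                    f"channel wider ({ch.width_mm} mm) than the scar patch ({patch_arc:.1f} mm)"
                )
            if not (self.healthy_si < ch.si_pct < self.core_si):
                raise ValidationError("channel SI must lie between healthy and core levels")

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "PhantomSpec":
        d = dict(d)
        if d.get("scar_patch") is None:
            d["scar_patch"] = None
        elif isinstance(d["scar_patch"], dict):
            sp = {k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in d["scar_patch"].items()}
            d["scar_patch"] = ScarPatchSpec(**sp)
        for key in ("channels", "decoys"):
            if key in d:
                d[key] = [
                    ChannelSpec(**{k: tuple(v) if isinstance(v, list) else v for k, v in ch.items()})
                    if isinstance(ch, dict) else ch
                    for ch in d[key]
                ]
        for key in ("endo_radii",):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return PhantomSpec(**d)


@dataclass
class GroundTruth:
    """Generator-side truth for every downstream oracle."""

    channel_vertex_sets: list  # per functional channel: endo-indexed vertex ids
    decoy_vertex_sets: list  # per decoy channel: endo-indexed vertex ids
    channel_voxel_counts: list  # per channel then decoy, number of voxels
    isthmus_egm_ids: list = field(default_factory=list)
    transform_true: RigidTransform | None = None
    landmarks_cmr: "LandmarkSet | None" = None
    spec: PhantomSpec | None = None


# ------------------------------------------------------ ellipsoid foot point
def ellipsoid_foot_points(points: np.ndarray, radii) -> tuple:
    """Closest point on an ellipsoid and the (unsigned) distance to it.

    Solves, per point, the largest root of
    ``sum_i (a_i^2 y_i^2 / (t + a_i^2)^2) = 1`` by bisection (the classic
    closest-point-on-ellipsoid formulation); the foot point is then
    ``p_i = a_i^2 y_i / (t + a_i^2)``.  Works for points inside and outside.

    Returns ``(foot, dist, inside)``.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    a2 = np.asarray(radii, dtype=np.float64) ** 2
    y = pts
    inside = np.sum(y**2 / a2, axis=1) < 1.0

    ay = np.sqrt(a2) * y
    # Bracket the largest root: g is strictly decreasing on (-min(a^2), inf).
    t_lo = np.full(len(y), -a2.min() * (1 - 1e-12))
    t_hi = np.maximum(np.linalg.norm(ay, axis=1), 1e-9)
    for _ in range(100):
        t_mid = 0.5 * (t_lo + t_hi)
        g = np.sum((ay / (t_mid[:, None] + a2[None, :])) ** 2, axis=1) - 1.0
        take_hi = g > 0
        t_lo = np.where(take_hi, t_mid, t_lo)
        t_hi = np.where(take_hi, t_hi, t_mid)
    t = 0.5 * (t_lo + t_hi)
    foot = a2[None, :] * y / (t[:, None] + a2[None, :])
    # Degenerate: point at the centre -> foot on the shortest axis.
    bad = ~np.isfinite(foot).all(axis=1)
    if np.any(bad):
        k = int(np.argmin(a2))
        fb = np.zeros((bad.sum(), 3))
        fb[:, k] = np.sqrt(a2[k])
        foot[bad] = fb
    dist = np.linalg.norm(y - foot, axis=1)
    return foot, dist, inside


def _wrap_angle(x: np.ndarray) -> np.ndarray:
    return (x + np.pi) % (2 * np.pi) - np.pi


def _shell_point(radii, u, theta):
    a, b, c = radii
    u = np.asarray(u, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    return np.stack(
        [a * np.sin(u) * np.cos(theta), b * np.sin(u) * np.sin(theta), -c * np.cos(u)],
        axis=-1,
    )


def _shell_normal(radii, pts):
    a, b, c = radii
    n = pts / np.asarray([a * a, b * b, c * c])
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    norm[norm == 0] = 1.0
    return n / norm


def _meridian_arclength(radii, u_grid):
    """Cumulative arc length (mm) along a meridian at theta=0."""
    a, _, c = radii
    uu = np.linspace(0, u_grid.max(), 2048)
    ds = np.sqrt((a * np.cos(uu)) ** 2 + (c * np.sin(uu)) ** 2)
    s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(uu))])
    return np.interp(u_grid, uu, s)


def _channel_membership(u, theta, frac, ch: ChannelSpec, patch: ScarPatchSpec, spec: PhantomSpec,
                        erode_mm: float = 0.0, frac_span=None):
    """Boolean membership of (u, theta, transmural fraction) in a channel strip.

    ``erode_mm`` shrinks the strip laterally and axially; used to define
    the conservative voxel-resolution ground truth.  ``frac_span``
    overrides the channel's own depth span (pass ``None`` to use it,
    or a span to test overlap against instead of pointwise inclusion).
    """
    a, b, c = spec.endo_radii
    a_eq = 0.5 * (a + b)
    u0 = math.radians(max(ch.u_deg[0], patch.u_deg[0]) if erode_mm else ch.u_deg[0])
    u1 = math.radians(min(ch.u_deg[1], patch.u_deg[1]) if erode_mm else ch.u_deg[1])
    if erode_mm:
        # convert the mm erosion to a polar-angle margin via the meridian metric
        r_mer = math.sqrt(a * c)
        du = erode_mm / r_mer
        u0, u1 = u0 + du, u1 - du
    in_u = (u >= u0) & (u <= u1)
    arc = np.abs(_wrap_angle(theta - math.radians(ch.theta_deg))) * a_eq * np.sin(u)
    in_arc = arc <= (ch.width_mm / 2.0 - erode_mm)
    if frac_span is None:
        lo, hi = ch.depth_span
        in_f = (frac >= lo) & (frac <= hi)
    else:
        lo, hi = ch.depth_span
        in_f = np.full(np.shape(u), (lo < frac_span[1]) and (hi > frac_span[0]))
    return in_u & in_arc & in_f


# ----------------------------------------------------------------- surfaces
def _build_shell_mesh(spec: PhantomSpec, offset_mm: float) -> TriSurface:
    a, b, c = spec.endo_radii
    u_max = math.acos(-spec.base_fraction)
    mer_len = _meridian_arclength(spec.endo_radii, np.asarray([u_max]))[0]
    n_u = max(8, int(round(mer_len / spec.mesh_edge_mm)))
    n_theta = max(12, int(round(2 * math.pi * 0.5 * (a + b) / spec.mesh_edge_mm)))

    u_rings = np.linspace(0.0, u_max, n_u + 1)[1:]
    thetas = -np.pi + 2 * np.pi * np.arange(n_theta) / n_theta

    verts = [np.asarray([[0.0, 0.0, -c]])]
    uu = [0.0]
    tt = [0.0]
    for u in u_rings:
        ring = _shell_point(spec.endo_radii, np.full(n_theta, u), thetas)
        verts.append(ring)
        uu.extend([u] * n_theta)
        tt.extend(thetas.tolist())
    vertices = np.vstack(verts)
    if offset_mm:
        normals = _shell_normal(spec.endo_radii, vertices)
        vertices = vertices + offset_mm * normals

    faces = []
    # apex fan
    for j in range(n_theta):
        jn = (j + 1) % n_theta
        faces.append([0, 1 + j, 1 + jn])
    # quad strips
    for i in range(n_u - 1):
        base0 = 1 + i * n_theta
        base1 = 1 + (i + 1) * n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            faces.append([base0 + j, base0 + jn, base1 + jn])
            faces.append([base0 + j, base1 + jn, base1 + j])
    # basal cap (valve stand-in)
    last = 1 + (n_u - 1) * n_theta
    ring = vertices[last : last + n_theta]
    center = ring.mean(axis=0)
    ci = len(vertices)
    vertices = np.vstack([vertices, center[None, :]])
    uu.append(u_max)
    tt.append(0.0)
    for j in range(n_theta):
        jn = (j + 1) % n_theta
        faces.append([ci, last + jn, last + j])
    faces = np.asarray(faces, dtype=np.int64)

    surf = TriSurface(vertices, faces)
    # ensure outward orientation (positive enclosed volume)
    if surf.as_trimesh().volume < 0:
        surf = TriSurface(vertices, faces[:, ::-1])
    valve = np.zeros(len(vertices), dtype=bool)
    valve[ci] = True
    surf.region_flags["valve"] = valve
    surf.scalar_channels["u_rad"] = np.asarray(uu)
    surf.scalar_channels["theta_rad"] = np.asarray(tt)
    return surf


# ------------------------------------------------------------------- volume
def _classify_points(pts: np.ndarray, spec: PhantomSpec):
    """SI value for arbitrary world points, plus per-channel membership."""
    a, b, c = spec.endo_radii
    zb = spec.base_fraction * c
    foot, dist, inside = ellipsoid_foot_points(pts, spec.endo_radii)
    in_wall = (~inside) & (dist <= spec.wall_thickness) & (pts[:, 2] <= zb)
    u = np.arccos(np.clip(-foot[:, 2] / c, -1.0, 1.0))
    theta = np.arctan2(foot[:, 1] / b, foot[:, 0] / a)
    frac = dist / spec.wall_thickness

    si = np.full(len(pts), spec.healthy_si)
    patch = spec.scar_patch
    if patch is not None:
        th0, th1 = math.radians(patch.theta_deg[0]), math.radians(patch.theta_deg[1])
        u0, u1 = math.radians(patch.u_deg[0]), math.radians(patch.u_deg[1])
        in_patch = (
            in_wall
            & (theta >= th0) & (theta <= th1)
            & (u >= u0) & (u <= u1)
            & (frac >= patch.depth[0]) & (frac <= patch.depth[1])
        )
        si[in_patch] = spec.core_si

    channel_masks = []
    for ch in list(spec.channels) + list(spec.decoys):
        m = in_wall & _channel_membership(u, theta, frac, ch, patch, spec)
        si[m] = ch.si_pct
        channel_masks.append(m)
    return si, channel_masks


def make_lv_phantom(spec: PhantomSpec):
    """Generate (SIVolume, endo, epi, GroundTruth) from a phantom spec.

    Deterministic for a fixed spec (including seed).
    """
    spec.validate()
    a, b, c = spec.endo_radii
    t = spec.wall_thickness
    h = spec.voxel_size

    endo = _build_shell_mesh(spec, 0.0)
    epi = _build_shell_mesh(spec, t)

    # voxel grid covering the epicardium with a 2-voxel margin
    rmax = max(a, b) + t + 2 * h
    zlo, zhi = -(c + t) - 2 * h, spec.base_fraction * c + 2 * h
    nx = int(math.ceil(2 * rmax / h))
    nz = int(math.ceil((zhi - zlo) / h))
    origin = np.asarray([-rmax, -rmax, zlo])
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = h
    affine[:3, 3] = origin

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(nx), np.arange(nz), indexing="ij")
    centers = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * h + origin
    si, channel_masks = _classify_points(centers, spec)
    array = si.reshape(nx, nx, nz)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        array = array + rng.normal(0.0, spec.noise_sd, size=array.shape)
    vol = SIVolume(array, affine)
    vol.validate()

    # ground truth: conservative (voxel-resolution) interior vertex sets
    u_v = endo.scalar_channels["u_rad"]
    th_v = endo.scalar_channels["theta_rad"]
    chan_sets, decoy_sets = [], []
    for ch in spec.channels:
        m = _channel_membership(
            u_v, th_v, 0.0, ch, spec.scar_patch, spec, erode_mm=h, frac_span=(0.0, 1.0)
        )
        chan_sets.append(np.flatnonzero(m))
    for ch in spec.decoys:
        m = _channel_membership(
            u_v, th_v, 0.0, ch, spec.scar_patch, spec, erode_mm=h, frac_span=(0.0, 1.0)
        )
        decoy_sets.append(np.flatnonzero(m))

    lm = _cmr_landmarks(spec, epi)
    gt = GroundTruth(
        channel_vertex_sets=chan_sets,
        decoy_vertex_sets=decoy_sets,
        channel_voxel_counts=[int(m.sum()) for m in channel_masks],
        landmarks_cmr=lm,
        spec=spec,
    )
    return vol, endo, epi, gt


def _cmr_landmarks(spec: PhantomSpec, epi: TriSurface) -> "LandmarkSet":
    a, b, c = spec.endo_radii
    u_max = math.acos(-spec.base_fraction)
    zb = spec.base_fraction * c
    pts = {
        "aortic_root": np.asarray([0.0, 0.45 * b, zb + 12.0]),
        "lv_apex": np.asarray([0.0, 0.0, -(c + spec.wall_thickness)]),
        "mitral_septal": _shell_point(spec.endo_radii, u_max, math.pi),
        "mitral_lateral": _shell_point(spec.endo_radii, u_max, 0.0),
    }
    return LandmarkSet({k: pts[k] for k in LANDMARK_NAMES})


# ----------------------------------------------------------- synthetic VT map
def _loop_waypoints(spec: PhantomSpec):
    """Reentrant-loop waypoints in (u, theta) radians: exit -> outer limb -> entrance -> channel."""
    ch = next(c for c in spec.channels if c.functional)
    patch = spec.scar_patch
    u_lo = math.radians(max(ch.u_deg[0], patch.u_deg[0]) + 3.0)
    u_hi = math.radians(min(ch.u_deg[1], patch.u_deg[1]) - 3.0)
    th_c = math.radians(ch.theta_deg)
    th_out = math.radians(patch.theta_deg[0] - 40.0)
    return [
        (u_lo, th_c),   # exit (apex-side channel end)
        (u_lo, th_out),
        (u_hi, th_out),
        (u_hi, th_c),   # entrance (basal channel end)
        (u_lo, th_c),   # back through the channel
    ], ch


def _sample_loop(spec: PhantomSpec, s_values: np.ndarray):
    """(u, theta) and segment index along the loop at normalized arc length s."""
    wps, ch = _loop_waypoints(spec)
    # fine polyline in parameter space, arc length measured in 3D
    fine_u, fine_th = [], []
    for (u0, t0), (u1, t1) in zip(wps[:-1], wps[1:]):
        k = 64
        lam = np.linspace(0, 1, k, endpoint=False)
        fine_u.append(u0 + lam * (u1 - u0))
        fine_th.append(t0 + lam * _wrap_angle(np.asarray([t1 - t0]))[0])
    fine_u = np.concatenate(fine_u)
    fine_th = np.concatenate(fine_th)
    pts = _shell_point(spec.endo_radii, fine_u, fine_th)
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    s_grid = np.concatenate([[0.0], np.cumsum(seg)])
    total = s_grid[-1]
    s_target = np.asarray(s_values) * total
    idx = np.clip(np.searchsorted(s_grid, s_target) - 1, 0, len(fine_u) - 1)
    # channel limb is the last quarter of the waypoint list (segment 3)
    n_per = 64
    on_channel = idx >= 3 * n_per
    return fine_u[idx], fine_th[idx], on_channel, total


def make_synthetic_vt_map(
    gt: GroundTruth,
    endo: TriSurface,
    cl_ms: float = 320.0,
    n_points: int = 300,
    seed: int = 0,
    coverage: float = 0.85,
    egm_noise_mm: float = 0.5,
    landmark_noise_mm: float = 0.5,
    transform: RigidTransform | None = None,
):
    """Simulate a reentrant VT activation map through the functional channel.

    Activation times are assigned arc-length-proportionally around the
    reentrant loop (exit -> outer limb -> entrance -> channel), spanning
    ``coverage`` of the cycle length; this reproduces the time geometry an
    activation map exposes without simulating electrophysiology.  Remote
    (off-circuit) points receive times from a wavefront spreading from the
    exit site.  The EP-space geometry is the CMR geometry moved by a known
    rigid transform plus point noise.

    Returns ``(ActivationMap, ep_landmarks, cmr_landmarks)`` and fills
    ``gt.isthmus_egm_ids`` / ``gt.transform_true``.
    """
    spec = gt.spec
    if spec is None or not any(c.functional for c in spec.channels):
        raise ValidationError("ground truth has no functional channel")
    if n_points < 20:
        raise ValidationError("n_points < 20: ROI construction degenerate")
    rng = np.random.default_rng(seed)

    if transform is None:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = math.radians(rng.uniform(8.0, 20.0))
        K = np.asarray(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)
        transform = RigidTransform(R, rng.uniform(-25.0, 25.0, size=3))
    gt.transform_true = transform

    a, b, c = spec.endo_radii
    t_earliest = -0.05 * cl_ms
    n_loop = max(12, n_points // 3)
    n_remote = n_points - n_loop

    s_loop = np.sort(rng.uniform(0.0, 1.0, n_loop))
    u_l, th_l, on_channel, _ = _sample_loop(spec, s_loop)
    # parameter-space jitter (sub-mm), then exact shell points
    a_eq = 0.5 * (a + b)
    u_l = u_l + rng.normal(0, 0.6 / math.sqrt(a * c), n_loop)
    th_l = th_l + rng.normal(0, 0.6 / a_eq, n_loop) / np.maximum(np.sin(u_l), 0.2)
    pos_l = _shell_point(spec.endo_radii, u_l, th_l)
    times_l = t_earliest + s_loop * coverage * cl_ms + rng.normal(0, 0.01 * cl_ms, n_loop)

    # remote points: area-weighted over the shell, wavefront times from the exit
    fa = endo.face_areas().copy()
    valve = endo.region_flags.get("valve")
    if valve is not None:
        fa[valve[endo.faces].any(axis=1)] = 0.0
    fidx = rng.choice(len(fa), size=n_remote, p=fa / fa.sum())
    bary = rng.dirichlet(np.ones(3), size=n_remote)
    pos_r = np.einsum("ij,ijk->ik", bary, endo.vertices[endo.faces[fidx]])
    wps, ch = _loop_waypoints(spec)
    exit_pt = _shell_point(spec.endo_radii, *wps[0])
    exit_vertex = int(np.argmin(np.linalg.norm(endo.vertices - exit_pt, axis=1)))
    dist = geodesic_distances(endo, np.asarray([exit_vertex]))
    d_r = dist[np.argmin(
        np.linalg.norm(endo.vertices[None, :, :] - pos_r[:, None, :], axis=2), axis=1
    )]
    d_max = np.nanmax(dist[np.isfinite(dist)])
    times_r = 0.35 * cl_ms * d_r / d_max + rng.normal(0, 0.02 * cl_ms, n_remote)

    positions = np.vstack([pos_l, pos_r])
    times = np.concatenate([times_l, times_r])

    # ground-truth isthmus labels: on the channel limb AND inside the eroded strip
    isthmus = np.zeros(len(positions), dtype=bool)
    strip = _channel_membership(
        u_l, th_l, 0.0, ch, spec.scar_patch, spec,
        erode_mm=spec.voxel_size, frac_span=(0.0, 1.0),
    )
    isthmus[:n_loop] = on_channel & strip
    gt.isthmus_egm_ids = np.flatnonzero(isthmus).tolist()

    ep_positions = transform.apply(positions) + rng.normal(0, egm_noise_mm, positions.shape)
    egms = [
        EGMRecord(egm_id=i, position=ep_positions[i], time_ms=float(times[i]), tag="activation")
        for i in range(len(positions))
    ]
    amap = ActivationMap(egms=egms, cl_ms=float(cl_ms))

    lm_cmr = gt.landmarks_cmr
    ep_pts = {
        k: transform.apply(v[None, :])[0] + rng.normal(0, landmark_noise_mm, 3)
        for k, v in lm_cmr.points.items()
    }
    lm_ep = LandmarkSet(ep_pts)
    return amap, lm_ep, lm_cmr
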