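"""Independent brute-force oracles used only by the tests.

These deliberately re-derive results through a different route than the
implementation (networkx instead of scipy.sparse.csgraph, per-face python
loops instead of vectorized barycentric sums, quadrature of the generating
geometry instead of voxel classification).
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

HEALTHY, BORDER, CORE = 0, 1, 2


def mesh_graph(faces: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    for a, b, c in faces:
        g.add_edge(int(a), int(b))
        g.add_edge(int(b), int(c))
        g.add_edge(int(c), int(a))
    return g


def flood_fill_components(faces: np.ndarray, mask: np.ndarray) -> list:
    """Connected components of masked vertices by explicit BFS."""
    g = mesh_graph(faces)
    seen: set = set()
    comps = []
    for start in np.flatnonzero(mask):
        start = int(start)
        if start in seen or start not in g:
            continue
        queue = [start]
        comp = set()
        while queue:
            v = queue.pop()
            if v in comp:
                continue
            comp.add(v)
            for w in g.neighbors(v):
                if mask[w] and w not in comp:
                    queue.append(w)
        seen |= comp
        comps.append(np.asarray(sorted(comp), dtype=np.int64))
    comps.sort(key=lambda a: int(a.min()))
    return comps


def oracle_corridor_components(
    faces: np.ndarray,
    labels: np.ndarray,
    include_enclosed: bool = False,
    min_vertices: int = 1,
    neutral: np.ndarray | None = None,
) -> list:
    """Qualifying corridor components by direct enumeration."""
    n = int(labels.shape[0])
    if neutral is None:
        neutral = np.zeros(n, dtype=bool)
    g = mesh_graph(faces)
    out = []
    for comp in flood_fill_components(faces, (labels == BORDER) & ~neutral):
        if len(comp) < min_vertices:
            continue
        comp_set = set(int(v) for v in comp)
        ring = set()
        for v in comp_set:
            for w in g.neighbors(v):
                if w not in comp_set:
                    ring.add(w)
        core_ring = [v for v in ring if labels[v] == CORE and not neutral[v]]
        if not core_ring:
            continue
        healthy_ring = [v for v in ring if labels[v] == HEALTHY and not neutral[v]]
        if not healthy_ring:
            if include_enclosed:
                out.append(comp)
            continue
        sub = g.subgraph(healthy_ring)
        if nx.number_connected_components(sub) >= 2:
            out.append(comp)
    return out


def oracle_vertex_set_area_cm2(faces: np.ndarray, vertices: np.ndarray, vertex_ids) -> float:
    """Barycentric area of a vertex set by per-face python accumulation."""
    sel = set(int(v) for v in vertex_ids)
    total = 0.0
    for f in faces:
        e1 = vertices[f[1]] - vertices[f[0]]
        e2 = vertices[f[2]] - vertices[f[0]]
        area = 0.5 * float(np.linalg.norm(np.cross(e1, e2)))
        k = sum(1 for v in f if int(v) in sel)
        total += area * k / 3.0
    return total / 100.0


def oracle_channel_volume_mm3(spec, channel, n_u: int = 400, n_d: int = 60) -> float:
    """Channel volume by quadrature over the offset-shell parameterization.

    The generator defines the strip by arc width at the *endocardial*
    radius, all transmural depths sharing the same angular window.  Volume
    is integrated in (u, depth) with the exact Jacobian of the offset map
    x = S(u, theta) + d n(u, theta): circumferential metric r(u, d) and
    meridian metric g(u) + d * dphi/du, where phi is the normal's polar
    angle.  Valid for rotationally symmetric shells (a == b).
    """
    a, b, c = spec.endo_radii
    assert abs(a - b) < 1e-9, "oracle assumes a rotationally symmetric shell"
    t = spec.wall_thickness
    u0 = math.radians(channel.u_deg[0])
    u1 = math.radians(channel.u_deg[1])
    d0, d1 = (channel.depth_span[0] * t, channel.depth_span[1] * t)

    us = np.linspace(u0, u1, n_u)
    sin_u, cos_u = np.sin(us), np.cos(us)
    g_mer = np.sqrt((a * cos_u) ** 2 + (c * sin_u) ** 2)
    n_rho = (sin_u / a) / np.sqrt((sin_u / a) ** 2 + (cos_u / c) ** 2)
    n_z = (cos_u / c) / np.sqrt((sin_u / a) ** 2 + (cos_u / c) ** 2)
    phi = np.arctan2(n_rho, n_z)
    dphi_du = np.gradient(phi, us)

    # angular half-width fixed by the endocardial arc criterion
    dtheta = channel.width_mm / (a * sin_u)  # full width in radians

    ds = np.linspace(d0, d1, n_d)
    du = (u1 - u0) / (n_u - 1)
    rows = []
    for d in ds:
        r_circ = a * sin_u + d * n_rho
        g_mer_d = g_mer + d * dphi_du
        rows.append(np.trapezoid(dtheta * r_circ * g_mer_d, dx=du))
    return float(np.trapezoid(np.asarray(rows), x=ds))
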