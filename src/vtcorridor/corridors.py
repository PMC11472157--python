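"""Tissue classification per SI cut-off range and corridor extraction.

A cut-off range is a (border-zone %, dense-core %) threshold pair on
normalized SI: tissue below the border-zone threshold is healthy, between
the two is heterogeneous scar (border zone), at or above the core
threshold is dense scar.  The default sweep holds 15 sequential ranges
starting at (33, 53) and advancing both thresholds in +1% steps at a
constant 20% width — the published method states the starting pair and the
sequential ordering; the step and width here are this package's documented
convention and are fully overridable.

A potential VT corridor on one layer is a connected component of
border-zone vertices that (a) touches dense core and (b) bridges at least
two separate healthy regions across its boundary ring (a conducting path
between healthier tissue, flanked by core).  Components entirely enclosed
by core are admitted only with ``include_enclosed``.  Vertices carrying a
neutral region flag (e.g. the valve) neither join healthy pieces nor act
as core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import TriSurface, ValidationError, connected_vertex_components
from .layering import WallLayerStack

HEALTHY, BORDER, CORE, INVALID = 0, 1, 2, -1

DEFAULT_SWEEP_START = (33.0, 53.0)
DEFAULT_SWEEP_SIZE = 15


@dataclass(frozen=True)
class CutoffRange:
    """One (border-zone, dense-core) threshold pair in % of reference SI."""

    range_id: int
    bz_pct: float
    core_pct: float

    def __post_init__(self) -> None:
        if not (0.0 < self.bz_pct < self.core_pct <= 100.0):
            raise ValidationError(
                f"invalid cut-off range ({self.bz_pct}, {self.core_pct})"
            )


@dataclass
class SweepPlan:
    """Ordered list of cut-off ranges swept over the layer stack."""

    ranges: list

    def __post_init__(self) -> None:
        ids = [r.range_id for r in self.ranges]
        if len(ids) != len(set(ids)):
            raise ValidationError("sweep range ids must be unique")
        bz = [r.bz_pct for r in self.ranges]
        if any(b2 <= b1 for b1, b2 in zip(bz[:-1], bz[1:])):
            raise ValidationError("sweep ranges must be strictly ordered by bz_pct")

    def __iter__(self):
        return iter(self.ranges)

    def __len__(self) -> int:
        return len(self.ranges)

    def __getitem__(self, i) -> CutoffRange:
        return self.ranges[i]

    def range_ids(self) -> list:
        return [r.range_id for r in self.ranges]


def default_sweep(
    n_ranges: int = DEFAULT_SWEEP_SIZE,
    start: tuple = DEFAULT_SWEEP_START,
    step_pct: float = 1.0,
) -> SweepPlan:
    """The default 15-range sweep: (33, 53), (34, 54), ... (47, 67)."""
    bz0, core0 = start
    width = core0 - bz0
    return SweepPlan(
        [
            CutoffRange(range_id=i + 1, bz_pct=bz0 + i * step_pct, core_pct=bz0 + i * step_pct + width)
            for i in range(n_ranges)
        ]
    )


@dataclass
class TissueLabelMap:
    """Per-vertex, per-layer tissue labels for one cut-off range."""

    labels: np.ndarray  # (n_layers, n_vertices) int8
    cutoff: CutoffRange
    fractions: np.ndarray


@dataclass
class Corridor:
    """A potential VT corridor: connected border-zone vertices on one layer."""

    vertex_ids: np.ndarray
    layer_fraction: float
    range_id: int
    area_cm2: float
    flanking: dict = field(default_factory=dict)  # ring label counts


# ------------------------------------------------------------ classification
def classify_tissue(stack: WallLayerStack, cutoff: CutoffRange) -> TissueLabelMap:
    """Label every (vertex, layer) as healthy / border / core / invalid.

    Boundary convention: border-zone is lower-inclusive,
    ``bz_pct <= SI < core_pct``; SI at the core threshold is core.
    """
    si = stack.si_pct
    labels = np.full(si.shape, HEALTHY, dtype=np.int8)
    labels[(si >= cutoff.bz_pct) & (si < cutoff.core_pct)] = BORDER
    labels[si >= cutoff.core_pct] = CORE
    labels[:, ~stack.valid] = INVALID
    labels[~np.isfinite(si)] = INVALID
    return TissueLabelMap(labels=labels, cutoff=cutoff, fractions=stack.fractions)


# --------------------------------------------------------------- extraction
def extract_corridors(
    label_map: TissueLabelMap,
    layer_fraction: float,
    surface: TriSurface,
    include_enclosed: bool = False,
    min_vertices: int = 5,
    neutral_flags: tuple = ("valve",),
) -> list:
    """Corridors on one layer for one cut-off range.

    Connected components of border-zone vertices qualify when they touch
    dense core and their boundary ring's healthy vertices split into at
    least two connected pieces (a border path joining two healthy regions
    through core), or — with ``include_enclosed`` — when the ring is core
    only.  Components smaller than ``min_vertices`` are partial-volume
    specks at the mesh/voxel scale, not corridors.
    """
    li = int(np.flatnonzero(np.isclose(label_map.fractions, layer_fraction))[0])
    labels = label_map.labels[li]
    adj = surface.vertex_adjacency()

    neutral = np.zeros(surface.n_vertices, dtype=bool)
    for name in neutral_flags:
        if name in surface.region_flags:
            neutral |= surface.region_flags[name]

    out = []
    for comp in connected_vertex_components(adj, (labels == BORDER) & ~neutral):
        if len(comp) < min_vertices:
            continue
        in_comp = np.zeros(surface.n_vertices, dtype=bool)
        in_comp[comp] = True
        ring_mask = np.asarray(adj[comp].sum(axis=0)).ravel() > 0
        ring_mask &= ~in_comp
        ring = np.flatnonzero(ring_mask)
        ring_labels = labels[ring]
        n_core = int(np.sum((ring_labels == CORE) & ~neutral[ring]))
        healthy_ring = ring_mask & (labels == HEALTHY) & ~neutral
        n_healthy = int(healthy_ring.sum())
        if n_core == 0:
            continue  # not adjacent to dense core
        if n_healthy == 0:
            qualifies = include_enclosed
        else:
            pieces = connected_vertex_components(adj, healthy_ring)
            qualifies = len(pieces) >= 2
        if not qualifies:
            continue
        out.append(
            Corridor(
                vertex_ids=comp,
                layer_fraction=float(layer_fraction),
                range_id=label_map.cutoff.range_id,
                area_cm2=surface.area_cm2(comp),
                flanking={"core": n_core, "healthy": n_healthy},
            )
        )
    return out


def corridor_area(corridor: Corridor, base: TriSurface) -> float:
    """Barycentric area of the corridor's vertex set, in cm^2."""
    return base.area_cm2(corridor.vertex_ids)


def sweep_corridors(
    stack: WallLayerStack,
    plan: SweepPlan,
    include_enclosed: bool = False,
    min_vertices: int = 5,
) -> list:
    """All corridors over every cut-off range and every layer."""
    out = []
    for cutoff in plan:
        lm = classify_tissue(stack, cutoff)
        for f in stack.fractions:
            out.extend(
                extract_corridors(
                    lm,
                    float(f),
                    stack.base,
                    include_enclosed=include_enclosed,
                    min_vertices=min_vertices,
                )
            )
    return out
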