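"""Surface footprints of corridors, with per-vertex provenance.

Corridors from the subendocardial half of the wall (layers at 10-50% of
wall thickness) project onto the endocardial surface; corridors from the
60-90% layers project onto the epicardium (septal vertices are reportable
separately through region flags).  Because all layers live on the
endocardial base mesh, projection is an index transfer — the epicardial
footprint reuses the base indexing through the wall correspondence, with
no resampling.

Provenance records, per member vertex, every (range_id, layer fraction)
that contributed, which is what the range-ranking optimizer consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import TriSurface, ValidationError
from .corridors import CutoffRange, SweepPlan
from .layering import WallLayerStack

ENDO_LAYERS = (0.1, 0.2, 0.3, 0.4, 0.5)
EPI_LAYERS = (0.6, 0.7, 0.8, 0.9)


@dataclass
class Footprint:
    """Per-vertex corridor membership on one surface."""

    surface_id: str  # "endo" or "epi"
    member: np.ndarray  # (n,) bool
    provenance: dict  # vertex id -> sorted list of (range_id, fraction)
    area_cm2: float
    vertex_areas_mm2: np.ndarray | None = None  # barycentric areas of the base mesh

    def member_ids(self) -> np.ndarray:
        return np.flatnonzero(self.member)


def _project(corridors, layers, surface: TriSurface, surface_id: str) -> Footprint:
    layers = tuple(float(x) for x in layers)
    n = surface.n_vertices
    member = np.zeros(n, dtype=bool)
    provenance: dict = {}
    for c in corridors:
        if not any(np.isclose(c.layer_fraction, layers)):
            raise ValidationError(
                f"corridor at layer {c.layer_fraction} not admissible for the "
                f"{surface_id} footprint (layers {layers})"
            )
        member[c.vertex_ids] = True
        for v in c.vertex_ids:
            provenance.setdefault(int(v), set()).add((c.range_id, c.layer_fraction))
    provenance = {v: sorted(s) for v, s in sorted(provenance.items())}
    return Footprint(
        surface_id=surface_id,
        member=member,
        provenance=provenance,
        area_cm2=surface.area_cm2(np.flatnonzero(member)),
        vertex_areas_mm2=surface.vertex_areas(),
    )


def project_endocardial(corridors, base: TriSurface, layers=ENDO_LAYERS) -> Footprint:
    """Union of subendocardial-layer corridors on the endocardial surface."""
    if any(f > 0.5 + 1e-9 for f in layers):
        raise ValidationError(
            "endocardial footprint only admits layers in the subendocardial half (<= 0.5)"
        )
    sel = [c for c in corridors if any(np.isclose(c.layer_fraction, layers))]
    return _project(sel, layers, base, "endo")


def project_epicardial(corridors, base: TriSurface, layers=EPI_LAYERS) -> Footprint:
    """Union of subepicardial-layer corridors, index-transferred to the epicardium."""
    if any(f < 0.5 + 1e-9 for f in layers):
        raise ValidationError(
            "epicardial footprint only admits layers in the subepicardial half (> 0.5)"
        )
    sel = [c for c in corridors if any(np.isclose(c.layer_fraction, layers))]
    return _project(sel, layers, base, "epi")


def split_footprints(corridors, base: TriSurface,
                     endo_layers=ENDO_LAYERS, epi_layers=EPI_LAYERS) -> tuple:
    """Both footprints under the 10-50% / 60-90% layer split."""
    return (
        project_endocardial(corridors, base, endo_layers),
        project_epicardial(corridors, base, epi_layers),
    )


def restrict_footprint(fp: Footprint, range_ids, plan: SweepPlan | None = None) -> Footprint:
    """Footprint restricted to corridors generated by the given ranges."""
    keep = set(int(r) for r in range_ids)
    if plan is not None:
        known = set(plan.range_ids())
        unknown = keep - known
        if unknown:
            raise ValidationError(f"unknown range ids {sorted(unknown)}")
    member = np.zeros_like(fp.member)
    provenance = {}
    for v, contribs in fp.provenance.items():
        kept = [rc for rc in contribs if rc[0] in keep]
        if kept:
            member[v] = True
            provenance[v] = kept
    if fp.vertex_areas_mm2 is not None:
        area = float(fp.vertex_areas_mm2[member].sum()) / 100.0
    else:
        # proportional estimate when the base mesh areas are unavailable
        area = fp.area_cm2 * member.sum() / max(int(fp.member.sum()), 1)
    return Footprint(
        surface_id=fp.surface_id,
        member=member,
        provenance=provenance,
        area_cm2=area,
        vertex_areas_mm2=fp.vertex_areas_mm2,
    )


def scar_footprint(stack: WallLayerStack, first_range: CutoffRange,
                   surface_id: str = "endo",
                   endo_layers=ENDO_LAYERS, epi_layers=EPI_LAYERS) -> Footprint:
    """Total-scar footprint: SI at or above the first range's border-zone threshold.

    The scar boundary is defined by the first cut-off range of the sweep;
    membership is the union across the layers belonging to the requested
    surface under the same 10-50% / 60-90% split used for corridors.
    """
    layers = tuple(endo_layers if surface_id == "endo" else epi_layers)
    sel = [stack.layer_index(f) for f in layers]
    scar = np.any(stack.si_pct[sel] >= first_range.bz_pct, axis=0)
    scar &= stack.valid
    member_ids = np.flatnonzero(scar)
    provenance = {int(v): [(first_range.range_id, 0.0)] for v in member_ids}
    return Footprint(
        surface_id=surface_id,
        member=scar,
        provenance=provenance,
        area_cm2=stack.base.area_cm2(member_ids),
        vertex_areas_mm2=stack.base.vertex_areas(),
    )
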