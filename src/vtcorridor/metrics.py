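"""Overlap, area, EGM-level sensitivity/specificity and ablation coverage.

EGM-level classification follows the isthmus-vs-footprint contingency: an
isthmus EGM on the corridor footprint is a true positive; off the
footprint it is a false negative *unless* another isthmus EGM of the same
characterized isthmus is on the footprint, in which case it is excluded
from the counts (the interdependence rule: detecting any part of an
isthmus detects that isthmus).  Non-isthmus EGMs on the footprint are
false positives, off it true negatives.  Sensitivity and specificity with
a zero denominator are reported as undefined (None), never as 0.

Ablation lesions (default diameter 6 mm) count as inside a corridor when
their centre vertex is a footprint member; the ablated fraction of the
corridor footprint uses the union of geodesic discs around the lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TriSurface, ValidationError, geodesic_distances
from .ep_roi import VTROI
from .footprint import Footprint


@dataclass
class ConfusionCounts:
    """EGM-level confusion counts under the interdependence rule."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    excluded: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn + self.excluded

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None


@dataclass
class OverlapReport:
    roi_area_cm2: float
    corridor_area_cm2: float
    scar_area_cm2: float
    overlap_area_cm2: float
    pct_roi_in_corridors: float
    pct_corridors_of_scar: float


@dataclass
class AblationLesionSet:
    """Ablation lesion centres assigned to base-mesh vertices."""

    center_vertices: np.ndarray
    diameter_mm: float = 6.0

    def __post_init__(self) -> None:
        self.center_vertices = np.asarray(self.center_vertices, dtype=np.int64)
        if self.diameter_mm <= 0:
            raise ValidationError("lesion diameter must be positive")


# ------------------------------------------------------------------ overlap
def overlap_report(roi: VTROI, corridor_fp: Footprint, scar_fp: Footprint,
                   base: TriSurface) -> OverlapReport:
    """Vertex-set overlap between the EP-defined ROI and the corridor footprint."""
    if len(corridor_fp.member) != base.n_vertices or len(scar_fp.member) != base.n_vertices:
        raise ValidationError("footprints and base mesh have mismatched vertex counts")
    roi_mask = np.zeros(base.n_vertices, dtype=bool)
    roi_mask[roi.vertex_ids] = True
    overlap = roi_mask & corridor_fp.member
    roi_area = base.area_cm2(np.flatnonzero(roi_mask))
    overlap_area = base.area_cm2(np.flatnonzero(overlap))
    pct_roi = 100.0 * overlap_area / roi_area if roi_area > 0 else 0.0
    pct_scar = (
        100.0 * corridor_fp.area_cm2 / scar_fp.area_cm2 if scar_fp.area_cm2 > 0 else 0.0
    )
    return OverlapReport(
        roi_area_cm2=roi_area,
        corridor_area_cm2=corridor_fp.area_cm2,
        scar_area_cm2=scar_fp.area_cm2,
        overlap_area_cm2=overlap_area,
        pct_roi_in_corridors=pct_roi,
        pct_corridors_of_scar=pct_scar,
    )


# ---------------------------------------------------------------- confusion
@dataclass
class EGMAssignment:
    """One classified EGM: base vertex, role, and isthmus grouping key."""

    egm_id: int
    vertex: int
    role: str  # isthmus / curvature / other
    isthmus_key: str | None = None  # same key = interdependent isthmus EGMs


def egm_confusion(
    assignments: list,
    corridor_fp: Footprint,
    curvature_as: str = "non_isthmus",
) -> ConfusionCounts:
    """EGM-level confusion counts against a corridor footprint.

    ``curvature_as`` selects the convention for curvature EGMs:
    ``non_isthmus`` (counted with healthy EGMs, the default), ``isthmus``
    (grouped with their isthmus), or ``exclude``.
    """
    if curvature_as not in ("non_isthmus", "isthmus", "exclude"):
        raise ValidationError(f"unknown curvature convention {curvature_as!r}")
    counts = ConfusionCounts()
    member = corridor_fp.member

    def effective_role(a: EGMAssignment) -> str | None:
        if a.role == "curvature":
            return {"non_isthmus": "other", "isthmus": "isthmus", "exclude": None}[curvature_as]
        return a.role

    usable = [a for a in assignments if a.vertex >= 0 and effective_role(a) is not None]
    # which isthmus groups were detected anywhere
    detected_groups = {
        a.isthmus_key
        for a in usable
        if effective_role(a) == "isthmus" and member[a.vertex]
    }
    for a in usable:
        on = bool(member[a.vertex])
        if effective_role(a) == "isthmus":
            if on:
                counts.tp += 1
            elif a.isthmus_key in detected_groups:
                counts.excluded += 1  # interdependence rule: counts 0
            else:
                counts.fn += 1
        else:
            if on:
                counts.fp += 1
            else:
                counts.tn += 1
    return counts


# ----------------------------------------------------------------- ablation
def ablation_overlap(
    lesions: AblationLesionSet, corridor_fp: Footprint, base: TriSurface
) -> tuple:
    """(percent of lesions inside corridors, percent of corridor area ablated)."""
    if lesions.center_vertices.size == 0:
        return 0.0, 0.0
    inside = corridor_fp.member[lesions.center_vertices]
    pct_lesions = 100.0 * float(inside.mean())
    radius = lesions.diameter_mm / 2.0
    d = geodesic_distances(base, lesions.center_vertices, limit=radius * 1.001)
    ablated = (d <= radius) & corridor_fp.member
    pct_area = (
        100.0 * base.area_cm2(np.flatnonzero(ablated)) / corridor_fp.area_cm2
        if corridor_fp.area_cm2 > 0
        else 0.0
    )
    return pct_lesions, pct_area


# ------------------------------------------------------------------- cohort
def cohort_summary(per_case: list) -> pd.DataFrame:
    """Median and IQR (linear-interpolation quantiles) across cases.

    ``per_case`` is a list of dicts of named metrics; returns a DataFrame
    indexed by metric with columns median/q1/q3/n.
    """
    if not per_case:
        raise ValidationError("cohort summary needs at least one case")
    df = pd.DataFrame(per_case)
    rows = {}
    for col in df.columns:
        vals = df[col].dropna().astype(float)
        rows[col] = {
            "median": float(np.quantile(vals, 0.5)),
            "q1": float(np.quantile(vals, 0.25)),
            "q3": float(np.quantile(vals, 0.75)),
            "n": int(len(vals)),
        }
    return pd.DataFrame(rows).T[["median", "q1", "q3", "n"]]
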