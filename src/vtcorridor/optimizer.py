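"""Ranking of SI cut-off ranges and top-k subset evaluation.

Each range's contribution in one case is the area of the EP-defined ROI
covered by vertices whose footprint provenance includes that range,
normalized by the ROI area; the cohort aggregate is the median (both the
denominator and the aggregator are configurable).  Ranges are ordered by
descending aggregate contribution, ties broken by range id.  Evaluating a
top-k subset restricts every case's footprint to those ranges and
recomputes areas, overlap retained and EGM-level sensitivity/specificity.

Ranking is in-sample (computed and evaluated on the same cases), as in
threshold-optimization practice; a leave-one-case-out mode quantifies the
optimism of that choice and is off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TriSurface, ValidationError
from .corridors import SweepPlan
from .ep_roi import VTROI
from .footprint import Footprint, restrict_footprint
from .metrics import egm_confusion

DEFAULT_KS = (15, 7, 5, 3, 1)


@dataclass
class CaseData:
    """One case: footprint with provenance, ROI, base mesh, classified EGMs."""

    case_id: str
    footprint: Footprint
    roi: VTROI
    base: TriSurface
    egm_assignments: list = field(default_factory=list)


@dataclass
class RangeRanking:
    per_case: pd.DataFrame  # rows: case_id, columns: range_id
    aggregate: pd.Series  # range_id -> aggregate contribution
    ordering: list  # range ids, best first


def _roi_mask(case: CaseData) -> np.ndarray:
    m = np.zeros(case.base.n_vertices, dtype=bool)
    m[case.roi.vertex_ids] = True
    return m


def rank_ranges(
    cases: list,
    plan: SweepPlan,
    aggregator: str = "median",
    denominator: str = "roi",
) -> RangeRanking:
    """Rank ranges by normalized ROI-overlap contribution across cases.

    contribution(case, r) = area(ROI ∩ vertices with provenance r) /
    area(ROI) (or / area(ROI ∩ footprint) with ``denominator='overlap'``).
    Cases with an empty ROI are excluded with a warning.
    """
    if aggregator not in ("median", "mean"):
        raise ValidationError(f"unknown aggregator {aggregator!r}")
    if denominator not in ("roi", "overlap"):
        raise ValidationError(f"unknown denominator {denominator!r}")
    rows = {}
    for case in cases:
        if len(case.roi.vertex_ids) == 0:
            warnings.warn(f"case {case.case_id}: empty ROI, excluded from ranking")
            continue
        va = case.base.vertex_areas()
        roi = _roi_mask(case)
        if denominator == "roi":
            denom = float(va[roi].sum())
        else:
            denom = float(va[roi & case.footprint.member].sum())
        contrib = {}
        by_range: dict = {r.range_id: [] for r in plan}
        for v, contribs in case.footprint.provenance.items():
            if roi[v]:
                for rid, _ in contribs:
                    by_range.setdefault(rid, []).append(v)
        for r in plan:
            verts = np.unique(np.asarray(by_range[r.range_id], dtype=np.int64))
            num = float(va[verts].sum()) if verts.size else 0.0
            contrib[r.range_id] = num / denom if denom > 0 else 0.0
        rows[case.case_id] = contrib
    if not rows:
        raise ValidationError("no cases with a nonempty ROI")
    per_case = pd.DataFrame(rows).T
    agg = per_case.median(axis=0) if aggregator == "median" else per_case.mean(axis=0)
    ordering = sorted(agg.index, key=lambda rid: (-agg[rid], rid))
    return RangeRanking(per_case=per_case, aggregate=agg, ordering=list(ordering))


def evaluate_topk(
    cases: list,
    ranking: RangeRanking,
    plan: SweepPlan,
    ks=DEFAULT_KS,
    curvature_as: str = "non_isthmus",
) -> pd.DataFrame:
    """Cohort metrics after restricting footprints to the top-k ranges.

    Returns one row per k with cohort medians of sensitivity, specificity,
    corridor area, and the fraction of the original ROI-corridor overlap
    retained; ``nulled_cases`` counts cases whose ROI-footprint overlap
    vanished at that k.
    """
    rows = []
    for k in ks:
        if k > len(plan):
            raise ValidationError(f"k={k} exceeds sweep size {len(plan)}")
        top = ranking.ordering[:k]
        sens, spec, areas, retained = [], [], [], []
        nulled = 0
        for case in cases:
            fp_k = restrict_footprint(case.footprint, top, plan)
            roi = _roi_mask(case)
            va = case.base.vertex_areas()
            full_overlap = float(va[roi & case.footprint.member].sum())
            k_overlap = float(va[roi & fp_k.member].sum())
            if full_overlap > 0 and k_overlap == 0:
                nulled += 1
            retained.append(k_overlap / full_overlap if full_overlap > 0 else np.nan)
            counts = egm_confusion(case.egm_assignments, fp_k, curvature_as=curvature_as)
            sens.append(np.nan if counts.sensitivity is None else counts.sensitivity)
            spec.append(np.nan if counts.specificity is None else counts.specificity)
            areas.append(fp_k.area_cm2)
        rows.append(
            {
                "k": k,
                "sensitivity": float(np.nanmedian(sens)),
                "specificity": float(np.nanmedian(spec)),
                "corridor_area_cm2": float(np.nanmedian(areas)),
                "overlap_retained": float(np.nanmedian(retained)),
                "nulled_cases": nulled,
            }
        )
    return pd.DataFrame(rows).set_index("k")
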