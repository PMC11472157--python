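"""Overlap reports, EGM confusion with the interdependence rule, ablation."""

import numpy as np
import pytest

import vtcorridor as vc
from vtcorridor.core import ValidationError
from vtcorridor.ep_roi import VTROI
from vtcorridor.footprint import Footprint
from vtcorridor.metrics import (
    AblationLesionSet,
    EGMAssignment,
    ablation_overlap,
    cohort_summary,
    egm_confusion,
    overlap_report,
)

from .conftest import make_flat_grid


def footprint_from_ids(grid, ids):
    member = np.zeros(grid.n_vertices, dtype=bool)
    member[np.asarray(ids, dtype=np.int64)] = True
    return Footprint(
        surface_id="endo",
        member=member,
        provenance={int(v): [(1, 0.3)] for v in ids},
        area_cm2=grid.area_cm2(ids),
        vertex_areas_mm2=grid.vertex_areas(),
    )


def roi_from_ids(grid, ids):
    ids = np.asarray(ids, dtype=np.int64)
    return VTROI(vertex_ids=ids, mode="activation", area_cm2=grid.area_cm2(ids))


def test_overlap_identity_and_disjoint(flat_grid):
    ids = np.arange(50, 90)
    fp = footprint_from_ids(flat_grid, ids)
    scar = footprint_from_ids(flat_grid, np.arange(40, 120))
    rep = overlap_report(roi_from_ids(flat_grid, ids), fp, scar, flat_grid)
    assert rep.pct_roi_in_corridors == pytest.approx(100.0)
    rep2 = overlap_report(roi_from_ids(flat_grid, np.arange(200, 240)), fp, scar, flat_grid)
    assert rep2.overlap_area_cm2 == 0.0
    assert rep2.pct_roi_in_corridors == 0.0


def test_half_overlapping_bands_give_half_percentage():
    grid = make_flat_grid(nx=41, ny=41, spacing=1.0)
    x = grid.vertices[:, 0]
    roi_ids = np.flatnonzero((x >= 10) & (x <= 20))
    fp_ids = np.flatnonzero((x >= 15) & (x <= 30))
    fp = footprint_from_ids(grid, fp_ids)
    scar = footprint_from_ids(grid, np.arange(grid.n_vertices))
    rep = overlap_report(roi_from_ids(grid, roi_ids), fp, scar, grid)
    # vertex-count oracle for the interior bands
    inter = np.intersect1d(roi_ids, fp_ids)
    expected = 100.0 * grid.area_cm2(inter) / grid.area_cm2(roi_ids)
    assert rep.pct_roi_in_corridors == pytest.approx(expected, rel=1e-9)
    assert abs(rep.pct_roi_in_corridors - 50.0) < 8.0


def test_confusion_all_correct(flat_grid):
    fp = footprint_from_ids(flat_grid, [1, 2, 3])
    assignments = [
        EGMAssignment(0, 1, "isthmus", "vt1"),
        EGMAssignment(1, 2, "isthmus", "vt1"),
        EGMAssignment(2, 100, "other"),
        EGMAssignment(3, 200, "other"),
    ]
    c = egm_confusion(assignments, fp)
    assert (c.tp, c.fp, c.tn, c.fn, c.excluded) == (2, 0, 2, 0, 0)
    assert c.sensitivity == 1.0 and c.specificity == 1.0


def test_interdependence_rule_excludes_covered_isthmus_egm(flat_grid):
    fp = footprint_from_ids(flat_grid, [1])
    assignments = [
        EGMAssignment(0, 1, "isthmus", "vt1"),   # on footprint
        EGMAssignment(1, 50, "isthmus", "vt1"),  # off, but vt1 already detected
    ]
    c = egm_confusion(assignments, fp)
    assert (c.tp, c.fn, c.excluded) == (1, 0, 1)
    assert c.sensitivity == 1.0
    # a second, undetected isthmus still produces false negatives
    assignments.append(EGMAssignment(2, 60, "isthmus", "vt2"))
    c2 = egm_confusion(assignments, fp)
    assert c2.fn == 1


def test_specificity_with_decoy_hits(flat_grid):
    fp = footprint_from_ids(flat_grid, [10, 11, 12])
    assignments = [
        EGMAssignment(i, v, "other")
        for i, v in enumerate([10, 11, 12, 100, 101, 102, 103, 104, 105, 106])
    ]
    c = egm_confusion(assignments, fp)
    assert c.specificity == pytest.approx(0.7)
    assert c.sensitivity is None  # no isthmus EGMs: undefined, not zero


def test_confusion_counts_conserve_total(flat_grid):
    rng = np.random.default_rng(0)
    fp = footprint_from_ids(flat_grid, rng.choice(flat_grid.n_vertices, 60, replace=False))
    assignments = [
        EGMAssignment(
            i,
            int(rng.integers(0, flat_grid.n_vertices)),
            rng.choice(["isthmus", "curvature", "other"]),
            "vt1",
        )
        for i in range(100)
    ]
    for conv in ("non_isthmus", "isthmus"):
        c = egm_confusion(assignments, fp, curvature_as=conv)
        assert c.total == 100
    c = egm_confusion(assignments, fp, curvature_as="exclude")
    n_curv = sum(a.role == "curvature" for a in assignments)
    assert c.total == 100 - n_curv


def test_ablation_lesion_accounting(flat_grid):
    fp = footprint_from_ids(flat_grid, np.arange(flat_grid.n_vertices))
    lesions = AblationLesionSet(center_vertices=[100, 150, 200])
    pct_lesions, pct_area = ablation_overlap(lesions, fp, flat_grid)
    assert pct_lesions == pytest.approx(100.0)
    assert pct_area > 0
    none = AblationLesionSet(center_vertices=np.asarray([], dtype=np.int64))
    assert ablation_overlap(none, fp, flat_grid) == (0.0, 0.0)


def test_single_lesion_disc_area_matches_flat_oracle():
    grid = make_flat_grid(nx=41, ny=41, spacing=1.0)
    center = 20 * 41 + 20
    fp = footprint_from_ids(grid, np.arange(grid.n_vertices))
    lesions = AblationLesionSet(center_vertices=[center], diameter_mm=6.0)
    _, pct_area = ablation_overlap(lesions, fp, grid)
    ablated_cm2 = pct_area / 100.0 * fp.area_cm2
    assert ablated_cm2 == pytest.approx(np.pi * 0.3**2, rel=0.10)


def test_cohort_summary_quantiles_and_invariance():
    cases = [{"m": float(v)} for v in range(1, 10)]
    df = cohort_summary(cases)
    assert df.loc["m", "median"] == 5.0
    assert df.loc["m", "q1"] == 3.0
    assert df.loc["m", "q3"] == 7.0
    assert df.loc["m", "n"] == 9
    perm = cohort_summary(list(reversed(cases)))
    assert perm.equals(df)
    single = cohort_summary([{"m": 4.2}])
    assert single.loc["m", "median"] == single.loc["m", "q1"] == single.loc["m", "q3"] == 4.2
    with pytest.raises(ValidationError):
        cohort_summary([])
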