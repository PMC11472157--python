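"""Sweep plans, tissue classification and corridor extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vtcorridor as vc
from vtcorridor.core import ValidationError
from vtcorridor.corridors import (
    BORDER,
    CORE,
    HEALTHY,
    Corridor,
    CutoffRange,
    SweepPlan,
    TissueLabelMap,
    classify_tissue,
    corridor_area,
    default_sweep,
    extract_corridors,
)
from vtcorridor.layering import WallLayerStack

from .conftest import make_flat_grid
from .oracles import oracle_corridor_components, oracle_vertex_set_area_cm2


def make_stack(surface, si_row):
    si = np.tile(np.asarray(si_row, dtype=float), (1, 1))
    return WallLayerStack(
        base=surface,
        fractions=np.asarray([0.5]),
        si_pct=si,
        valid=np.ones(surface.n_vertices, dtype=bool),
        norm_reference=100.0,
    )


def test_default_sweep_matches_published_start_and_count():
    plan = default_sweep()
    assert len(plan) == 15
    assert (plan[0].bz_pct, plan[0].core_pct) == (33.0, 53.0)
    assert all(r.core_pct - r.bz_pct == 20.0 for r in plan)
    assert plan.range_ids() == list(range(1, 16))


def test_custom_sweep_honored_verbatim():
    ranges = [CutoffRange(i, 30.0 + 2 * i, 60.0 + 2 * i) for i in range(7)]
    plan = SweepPlan(ranges)
    assert list(plan) == ranges
    with pytest.raises(ValidationError, match="unique"):
        SweepPlan([CutoffRange(1, 30, 50), CutoffRange(1, 35, 55)])
    with pytest.raises(ValidationError, match="ordered"):
        SweepPlan([CutoffRange(1, 40, 60), CutoffRange(2, 35, 55)])


def test_classification_boundary_conventions(flat_grid):
    stack = make_stack(flat_grid, np.full(flat_grid.n_vertices, 20.0))
    rng = CutoffRange(1, 33.0, 53.0)
    for si, expected in [(20.0, HEALTHY), (33.0, BORDER), (52.999, BORDER), (53.0, CORE)]:
        stack.si_pct[:] = si
        labels = classify_tissue(stack, rng).labels
        assert np.all(labels == expected)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    si=st.lists(st.floats(0, 110), min_size=5, max_size=50),
    bz=st.floats(10, 79),
    width=st.floats(1, 20),
)
def test_labels_partition_valid_vertices(si, bz, width):
    grid = make_flat_grid(nx=2, ny=len(si) // 2 + 3)
    row = np.resize(np.asarray(si), grid.n_vertices)
    stack = make_stack(grid, row)
    rng = CutoffRange(1, bz, min(bz + width, 100.0))
    labels = classify_tissue(stack, rng).labels
    n_labelled = sum(int(np.sum(labels == lab)) for lab in (HEALTHY, BORDER, CORE))
    assert n_labelled == labels.size


def test_raising_bz_never_increases_border_count(phantom_imaging):
    stack = phantom_imaging.stack
    core = 67.0
    prev = None
    for bz in (33.0, 38.0, 43.0, 47.0):
        labels = classify_tissue(stack, CutoffRange(1, bz, core)).labels
        n_border = int(np.sum(labels == BORDER))
        if prev is not None:
            assert n_border <= prev
        prev = n_border


# ------------------------------------------------------------- extraction
def grid_labels(grid, si_values):
    stack = make_stack(grid, si_values)
    return classify_tissue(stack, CutoffRange(1, 33.0, 53.0))


def test_all_healthy_layer_yields_no_corridors(flat_grid):
    lm = grid_labels(flat_grid, np.full(flat_grid.n_vertices, 10.0))
    assert extract_corridors(lm, 0.5, flat_grid) == []


def test_straight_channel_through_core_is_one_corridor():
    grid = make_flat_grid(nx=21, ny=21, spacing=1.0)
    x = grid.vertices[:, 0]
    y = grid.vertices[:, 1]
    si = np.full(grid.n_vertices, 10.0)
    core_zone = (y >= 5) & (y <= 15)
    si[core_zone] = 90.0
    channel = core_zone & (np.abs(x - 10) <= 2)
    si[channel] = 43.0
    lm = grid_labels(grid, si)
    cors = extract_corridors(lm, 0.5, grid)
    assert len(cors) == 1
    assert set(np.flatnonzero(channel)).issubset(set(cors[0].vertex_ids.tolist()))


def test_scar_rim_band_is_not_a_corridor():
    # border strip glued to one side of the core block: healthy ring is one arc
    grid = make_flat_grid(nx=21, ny=21, spacing=1.0)
    y = grid.vertices[:, 1]
    si = np.full(grid.n_vertices, 10.0)
    si[(y >= 8) & (y <= 14)] = 90.0
    si[(y >= 5) & (y < 8)] = 43.0  # rim between healthy and core
    lm = grid_labels(grid, si)
    assert extract_corridors(lm, 0.5, grid) == []


def test_core_enclosed_component_needs_flag():
    grid = make_flat_grid(nx=15, ny=15, spacing=1.0)
    x, y = grid.vertices[:, 0], grid.vertices[:, 1]
    si = np.full(grid.n_vertices, 90.0)
    blob = (np.abs(x - 7) <= 2) & (np.abs(y - 7) <= 2)
    si[blob] = 43.0
    lm = grid_labels(grid, si)
    assert extract_corridors(lm, 0.5, grid) == []
    cors = extract_corridors(lm, 0.5, grid, include_enclosed=True)
    assert len(cors) == 1


def test_phantom_channel_recovered_as_single_corridor(phantom_imaging):
    pi = phantom_imaging
    chan = set(pi.gt.channel_vertex_sets[0].tolist())
    # in the range where the channel is border zone, one corridor holds >= 95% of it
    best = 0.0
    for c in pi.corridors:
        got = len(chan & set(c.vertex_ids.tolist())) / len(chan)
        best = max(best, got)
    assert best >= 0.95


def test_extraction_matches_bruteforce_oracle_on_random_meshes():
    rng = np.random.default_rng(42)
    for trial in range(12):
        nx = int(rng.integers(6, 15))
        ny = int(rng.integers(6, 15))
        grid = make_flat_grid(nx=nx, ny=ny, spacing=1.0)
        si = rng.choice([10.0, 43.0, 90.0], size=grid.n_vertices, p=[0.4, 0.35, 0.25])
        lm = grid_labels(grid, si)
        for enclosed in (False, True):
            ours = extract_corridors(lm, 0.5, grid, include_enclosed=enclosed, min_vertices=1)
            oracle = oracle_corridor_components(
                grid.faces, lm.labels[0], include_enclosed=enclosed, min_vertices=1
            )
            ours_sets = sorted(tuple(c.vertex_ids.tolist()) for c in ours)
            oracle_sets = sorted(tuple(c.tolist()) for c in oracle)
            assert ours_sets == oracle_sets


def test_valve_flag_is_neutral_in_ring_logic():
    grid = make_flat_grid(nx=21, ny=11, spacing=1.0)
    x, y = grid.vertices[:, 0], grid.vertices[:, 1]
    si = np.full(grid.n_vertices, 90.0)
    channel = np.abs(x - 10) <= 1.5
    si[channel] = 43.0
    si[x <= 4] = 10.0  # healthy on the left only
    lm = grid_labels(grid, si)
    # without flags: only one healthy region -> no corridor
    assert extract_corridors(lm, 0.5, grid) == []
    # flagging the right edge as valve must NOT turn it into a healthy piece
    grid.region_flags["valve"] = x >= 16
    lm2 = grid_labels(grid, si)
    assert extract_corridors(lm2, 0.5, grid) == []


# ------------------------------------------------------------------ areas
def test_corridor_area_unit_square():
    # 1 cm x 1 cm square split in two triangles
    verts = np.asarray([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]], dtype=float)
    faces = np.asarray([[0, 1, 2], [0, 2, 3]])
    square = vc.TriSurface(verts, faces)
    c = Corridor(np.arange(4), 0.5, 1, 0.0)
    assert corridor_area(c, square) == pytest.approx(1.0, rel=1e-12)
    empty = Corridor(np.asarray([], dtype=np.int64), 0.5, 1, 0.0)
    assert corridor_area(empty, square) == 0.0


def test_area_matches_per_face_oracle():
    rng = np.random.default_rng(11)
    grid = make_flat_grid(nx=8, ny=9, spacing=1.3)
    for _ in range(10):
        ids = np.flatnonzero(rng.random(grid.n_vertices) < 0.5)
        ours = grid.area_cm2(ids)
        oracle = oracle_vertex_set_area_cm2(grid.faces, grid.vertices, ids)
        assert ours == pytest.approx(oracle, rel=1e-9, abs=1e-12)
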