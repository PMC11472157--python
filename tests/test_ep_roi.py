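"""Activation window, ROI construction and landmark registration."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import vtcorridor as vc
from vtcorridor.core import RigidTransform, ValidationError
from vtcorridor.ep_roi import build_roi, fit_landmark_transform, select_roi_egms, transfer_egms
from vtcorridor.io_formats import ActivationMap, EGMRecord

from .conftest import make_flat_grid


def act_map(times, positions=None, cl_ms=300.0):
    n = len(times)
    if positions is None:
        positions = np.zeros((n, 3))
    egms = [
        EGMRecord(i, positions[i], float(times[i]), "activation") for i in range(n)
    ]
    return ActivationMap(egms=egms, cl_ms=cl_ms)


def test_window_rule_direct_evaluation():
    # cl=300, latest=140, earliest=-120: window is t >= 35 or t <= -90
    amap = act_map([140.0, -120.0, 60.0, 0.0, -100.0])
    win = select_roi_egms(amap)
    assert win.tolist() == [True, True, True, False, True]


def test_window_measure_is_45_percent_of_cycle():
    rng = np.random.default_rng(123)
    cl = 300.0
    times = rng.uniform(0.0, cl, 1000)
    win = select_roi_egms(act_map(times, cl_ms=cl))
    assert win.mean() == pytest.approx(0.45, abs=0.03)


def test_window_requires_cycle_length():
    amap = act_map([0.0, 10.0])
    amap.cl_ms = None
    with pytest.raises(ValidationError, match="cycle length"):
        select_roi_egms(amap)


# ----------------------------------------------------------- registration
def make_landmarks(offset=np.zeros(3)):
    return vc.LandmarkSet(
        {
            "aortic_root": np.asarray([0.0, 10.0, 32.0]) + offset,
            "lv_apex": np.asarray([0.0, 0.0, -50.0]) + offset,
            "mitral_septal": np.asarray([-19.0, 0.0, 20.0]) + offset,
            "mitral_lateral": np.asarray([19.0, 0.0, 20.0]) + offset,
        }
    )


def test_identity_fit_has_zero_residual():
    lm = make_landmarks()
    tf, rms = fit_landmark_transform(lm, lm)
    assert rms == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)
    assert np.allclose(tf.translation, 0.0, atol=1e-9)


def test_synthesized_transform_recovered_exactly():
    rng = np.random.default_rng(5)
    src = make_landmarks()
    for _ in range(10):
        true = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.uniform(-30, 30, 3))
        dst = vc.LandmarkSet({k: true.apply(v[None, :])[0] for k, v in src.points.items()})
        tf, rms = fit_landmark_transform(src, dst)
        assert rms < 1e-9
        assert np.abs(tf.rotation - true.rotation).max() < 1e-6
        assert np.abs(tf.translation - true.translation).max() < 1e-6


def test_similarity_fit_recovers_scale():
    src = make_landmarks()
    true = RigidTransform(np.eye(3), np.asarray([5.0, -3.0, 2.0]), scale=1.08)
    dst = vc.LandmarkSet({k: true.apply(v[None, :])[0] for k, v in src.points.items()})
    tf, rms = fit_landmark_transform(src, dst, allow_scale=True)
    assert tf.scale == pytest.approx(1.08, abs=1e-9)
    assert rms < 1e-9


def test_noisy_landmarks_rotation_error_within_two_degrees():
    src = make_landmarks()
    errors = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        true = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.uniform(-30, 30, 3))
        dst = vc.LandmarkSet(
            {
                k: true.apply(v[None, :])[0] + rng.normal(0, 0.5, 3)
                for k, v in src.points.items()
            }
        )
        tf, rms = fit_landmark_transform(src, dst)
        rel = tf.rotation @ true.rotation.T
        angle = np.degrees(np.arccos(np.clip((np.trace(rel) - 1) / 2, -1, 1)))
        errors.append(angle)
    assert np.median(errors) <= 2.0


def test_collinear_landmarks_rejected():
    lm = vc.LandmarkSet(
        {
            "aortic_root": [0.0, 0.0, 0.0],
            "lv_apex": [0.0, 0.0, 10.0],
            "mitral_septal": [0.0, 0.0, 20.0],
            "mitral_lateral": [0.0, 0.0, 30.0],
        }
    )
    with pytest.raises(ValidationError, match="collinear"):
        fit_landmark_transform(lm, lm)


# ----------------------------------------------------------------- transfer
def test_transfer_maps_vertex_coincident_egm_exactly(flat_grid):
    pos = flat_grid.vertices[17]
    amap = act_map([10.0], positions=pos[None, :])
    out = transfer_egms(amap, RigidTransform.identity(), flat_grid)
    assert out[0] == (17, pytest.approx(0.0, abs=1e-12))


def test_transfer_flags_far_egm_unmapped(flat_grid):
    pos = flat_grid.vertices[0] + np.asarray([0.0, 0.0, 50.0])
    amap = act_map([10.0], positions=pos[None, :])
    with pytest.warns(UserWarning, match="excluded"):
        out = transfer_egms(amap, RigidTransform.identity(), flat_grid)
    assert out[0][0] == -1


# ---------------------------------------------------------------------- ROI
def test_coincident_earliest_latest_gives_single_disc(flat_grid):
    pos = np.tile(flat_grid.vertices[220], (2, 1))
    amap = act_map([0.0, 1.0], positions=pos)
    assignments = transfer_egms(amap, RigidTransform.identity(), flat_grid)
    roi = build_roi(amap, "activation", flat_grid, assignments, radius_mm=5.0)
    d = np.linalg.norm(flat_grid.vertices[roi.vertex_ids] - flat_grid.vertices[220], axis=1)
    assert d.max() <= 5.0 + 1e-9
    assert roi.area_cm2 > 0


def test_pacemap_band_area_matches_stadium_oracle():
    grid = make_flat_grid(nx=61, ny=41, spacing=1.0)
    # entrance and exit 20 mm apart in the middle of the sheet
    p0 = np.asarray([20.0, 20.0, 0.0])
    p1 = np.asarray([40.0, 20.0, 0.0])
    egms = [
        EGMRecord(0, p0, None, "pacemap_entrance"),
        EGMRecord(1, p1, None, "pacemap_exit"),
    ]
    amap = ActivationMap(egms=egms, cl_ms=None)
    assignments = transfer_egms(amap, RigidTransform.identity(), grid)
    roi = build_roi(amap, "pacemap", grid, assignments, radius_mm=5.0)
    stadium = (np.pi * 25.0 + 20.0 * 10.0) / 100.0  # cm^2
    assert roi.area_cm2 == pytest.approx(stadium, rel=0.10)


def test_entrainment_chain_connects_points(flat_grid):
    ids = [5, 200, 395]
    egms = [
        EGMRecord(i, flat_grid.vertices[v], None, "entrainment_isthmus")
        for i, v in enumerate(ids)
    ]
    amap = ActivationMap(egms=egms, cl_ms=None)
    assignments = transfer_egms(amap, RigidTransform.identity(), flat_grid)
    roi = build_roi(amap, "entrainment", flat_grid, assignments, radius_mm=4.0)
    from vtcorridor.core import connected_vertex_components

    mask = np.zeros(flat_grid.n_vertices, dtype=bool)
    mask[roi.vertex_ids] = True
    comps = connected_vertex_components(flat_grid.vertex_adjacency(), mask)
    assert len(comps) == 1


def test_roi_mode_validation(flat_grid):
    amap = ActivationMap(
        egms=[EGMRecord(0, flat_grid.vertices[0], None, "entrainment_isthmus")],
        cl_ms=None,
    )
    assignments = transfer_egms(amap, RigidTransform.identity(), flat_grid)
    with pytest.raises(ValidationError, match=">= 2"):
        build_roi(amap, "entrainment", flat_grid, assignments)
    with pytest.raises(ValidationError, match="unknown ROI mode"):
        build_roi(amap, "voltage", flat_grid, assignments)


def test_phantom_roi_overlaps_ground_truth_channel(vt_case):
    chan = set(vt_case.gt.channel_vertex_sets[0].tolist())
    roi_set = set(vt_case.roi.vertex_ids.tolist())
    assert len(chan & roi_set) > 0
    assert vt_case.report["pct_roi_in_corridors"] > 10.0
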