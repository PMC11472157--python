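"""Shared fixtures: phantoms, pipelines, and small analytic meshes."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest
import trimesh

import vtcorridor as vc
from vtcorridor.corridors import default_sweep, sweep_corridors
from vtcorridor.footprint import scar_footprint, split_footprints
from vtcorridor.layering import normalize_reference, sample_layers, wall_voxel_mask


def make_flat_grid(nx: int = 21, ny: int = 21, spacing: float = 2.0) -> vc.TriSurface:
    """Flat rectangular triangle grid in the z=0 plane (mm)."""
    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.stack([xx.ravel(), yy.ravel(), np.zeros(nx * ny)], axis=1)
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            faces.append([a, b, b + 1])
            faces.append([a, b + 1, a + 1])
    return vc.TriSurface(verts, np.asarray(faces))


def make_sphere(radius: float, subdivisions: int = 3) -> vc.TriSurface:
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return vc.TriSurface(np.asarray(m.vertices), np.asarray(m.faces))


def criterion_spec(seed: int = 0) -> vc.PhantomSpec:
    """Noiseless single-channel phantom: channel 43, core 70, healthy 15."""
    return vc.PhantomSpec(
        channels=[vc.ChannelSpec(si_pct=43.0)],
        decoys=[],
        core_si=70.0,
        healthy_si=15.0,
        noise_sd=0.0,
        seed=seed,
    )


def run_imaging(spec: vc.PhantomSpec) -> SimpleNamespace:
    """Phantom -> correspondence -> stack -> sweep -> footprints (no EP side)."""
    vol, endo, epi, gt = vc.make_lv_phantom(spec)
    corr = vc.build_correspondence(endo, epi)
    ref = normalize_reference(vol, wall_voxel_mask(vol, endo, corr))
    stack = sample_layers(vol, endo, corr, norm_reference=ref)
    plan = default_sweep()
    corridors = sweep_corridors(stack, plan)
    endo_fp, epi_fp = split_footprints(corridors, endo)
    scar_fp = scar_footprint(stack, plan[0])
    return SimpleNamespace(
        spec=spec, vol=vol, endo=endo, epi=epi, gt=gt, corr=corr, stack=stack,
        plan=plan, corridors=corridors, endo_fp=endo_fp, epi_fp=epi_fp, scar_fp=scar_fp,
    )


@pytest.fixture(scope="session")
def phantom_imaging() -> SimpleNamespace:
    return run_imaging(criterion_spec(seed=0))


@pytest.fixture(scope="session")
def vt_case() -> vc.CaseResult:
    """Full pipeline on the criterion phantom including the simulated VT map."""
    return vc.run_phantom_case(criterion_spec(seed=0))


@pytest.fixture(scope="session")
def cohort():
    """Five-case phantom cohort with decoy-only high ranges, plus optimization."""
    results, ranking, table = vc.run_cohort(n_cases=5, base_seed=10)
    return SimpleNamespace(results=results, ranking=ranking, table=table)


@pytest.fixture()
def flat_grid() -> vc.TriSurface:
    return make_flat_grid()
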