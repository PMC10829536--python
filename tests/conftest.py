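"""Shared fixtures.

Expensive solves are session-scoped and shared between unit, property and
acceptance tests to keep the suite inside a CI budget.
"""

from __future__ import annotations

import numpy as np
import pytest

from dbsvta.field_solver import SinkSpec, solve_potential
from dbsvta.grid import VoxelGrid
from dbsvta.lead_model import LeadSpec, Trajectory, build_lead, rasterize_lead
from dbsvta.model import EXTERIOR, GRAY_MATTER, LEAD_ACTIVE, TissueModel
from dbsvta.oracles import sphere_contact_phantom, sphere_sink
from dbsvta.outcome_report import PipelineConfig, run_pipeline
from dbsvta.vta_metric import VTAConfig


@pytest.fixture(scope="session")
def small_ball_solution():
    """Homogeneous ball (R=30 mm, h=1.5 mm), spherical contact a=2 mm,
    grounded surface shell: cheap solve with a closed-form answer."""
    h, R = 1.5, 30.0
    half = R + 2 * h
    grid = VoxelGrid.from_bounds((-half,) * 3, (half,) * 3, h, dtype=np.int16,
                                 fill=EXTERIOR)
    model = sphere_contact_phantom(grid, R, contact_radius=2.0, sigma=0.12)
    sink = sphere_sink(grid, R)
    fieldv = solve_potential(model, current=5.5e-3, sink=sink)
    return dict(model=model, sink=sink, field=fieldv, sigma=0.12,
                current=5.5e-3, domain_radius=R, contact_radius=2.0)


@pytest.fixture(scope="session")
def ring_lead_solution():
    """Directional-lead ring contact in a homogeneous ball (R=40, h=1.0):
    shared by impedance, refinement and calibration tests."""
    h, R, sigma = 1.0, 40.0, 0.25
    half = R + 2 * h
    grid = VoxelGrid.from_bounds((-half,) * 3, (half,) * 3, h, dtype=np.int16,
                                 fill=EXTERIOR)
    x, y, z = grid.coordinate_mesh()
    r = np.sqrt(x * x + y * y + z * z)
    labels = np.full(grid.shape, EXTERIOR, dtype=np.int16)
    labels[r <= R] = GRAY_MATTER
    model = TissueModel(labels=grid.like(labels),
                        conductivity={EXTERIOR: 0.0, GRAY_MATTER: sigma})
    traj = Trajectory(tip=np.array([0.0, 0.0, -0.75]),
                      direction=np.array([0.0, 0.0, 1.0]))
    spec = LeadSpec.abbott_6172()
    geom = build_lead(traj, spec)
    rasterized = rasterize_lead(geom, model, active_id=1, allow_partial=True)
    sink = sphere_sink(grid, R)
    fieldv = solve_potential(rasterized, current=1e-3, sink=sink)

    def rerasterize(fine_grid):
        labs = np.full(fine_grid.shape, EXTERIOR, dtype=np.int16)
        xx, yy, zz = fine_grid.coordinate_mesh()
        rr = np.sqrt(xx * xx + yy * yy + zz * zz)
        labs[rr <= R] = GRAY_MATTER
        m = TissueModel(labels=fine_grid.like(labs),
                        conductivity={EXTERIOR: 0.0, GRAY_MATTER: sigma})
        return rasterize_lead(geom, m, active_id=1, allow_partial=True)

    return dict(model=rasterized, bare_model=model, sink=sink, field=fieldv,
                geom=geom, sigma=sigma, current=1e-3, domain_radius=R,
                rerasterize=rerasterize)


#: coarse desk/CI pipeline settings shared by outcome + acceptance tests
TEST_PIPELINE_KWARGS = dict(
    phantom_spacing=2.5,
    refine_box_mm=14.0,
    refine_spacing=0.5,
    vta=VTAConfig(box_mm=12.0, spacing_mm=0.25),
)


def make_test_pipeline_config(patient_id: int, sides: tuple[str, ...],
                              out_dir=None, seed: int = 0) -> PipelineConfig:
    return PipelineConfig(patient_id=patient_id, sides=sides, seed=seed,
                          out_dir=out_dir, **TEST_PIPELINE_KWARGS)


@pytest.fixture(scope="session")
def pipeline_p1_left(tmp_path_factory):
    out = tmp_path_factory.mktemp("p1_left")
    cfg = make_test_pipeline_config(1, ("left",), out_dir=str(out))
    table = run_pipeline(cfg)
    return dict(table=table, out=out, cfg=cfg)


@pytest.fixture(scope="session")
def pipeline_right_both_patients(tmp_path_factory):
    """Right-side runs for both patients (ordering property)."""
    tables = {}
    for pid in (1, 2):
        cfg = make_test_pipeline_config(pid, ("right",))
        tables[pid] = run_pipeline(cfg)
    return tables
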