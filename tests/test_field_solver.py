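import numpy as np
import pytest

from dbsvta.field_solver import (
    SinkSpec,
    SolverError,
    analytic_point_source,
    compute_impedance,
    contact_current,
    refine_local,
    solve_potential,
)
from dbsvta.grid import VoxelGrid
from dbsvta.model import (
    CSF,
    EXTERIOR,
    GRAY_MATTER,
    LEAD_ACTIVE,
    WHITE_MATTER,
    TissueModel,
)
from dbsvta.oracles import sphere_contact_phantom, sphere_sink


def box_model(sigma=0.12, spacing=1.0, half=10.0, contact_radius=1.5):
    """Conductive box with a central ball contact; sink on the bottom face."""
    g = VoxelGrid.from_bounds((-half,) * 3, (half,) * 3, spacing,
                              dtype=np.int16, fill=GRAY_MATTER)
    x, y, z = g.coordinate_mesh()
    r = np.sqrt(x * x + y * y + z * z)
    g.values[r <= contact_radius] = LEAD_ACTIVE
    return TissueModel(labels=g, conductivity={
        GRAY_MATTER: sigma, LEAD_ACTIVE: 4e6, EXTERIOR: 0.0,
    })


class TestAnalyticPointSource:
    def test_printed_value(self):
        v = analytic_point_source(5.5e-3, 0.12, np.array([3.0, 0.0, 0.0]))
        assert v[0] == pytest.approx(1.2158, rel=1e-4)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError, match="r = 0"):
            analytic_point_source(1e-3, 0.1, np.zeros(3))

    def test_inverse_sigma_scaling(self):
        p = np.array([2.0, 1.0, 2.0])
        assert analytic_point_source(1e-3, 0.1, p)[0] == pytest.approx(
            2 * analytic_point_source(1e-3, 0.2, p)[0])

    def test_decay_to_zero(self):
        far = analytic_point_source(1e-3, 0.1, np.array([1e6, 0, 0]))[0]
        assert far < 1e-6


class TestSolvePotential:
    def test_maximum_principle(self, small_ball_solution):
        f = small_ball_solution["field"]
        cond = small_ball_solution["field"].conductive.values
        phi = f.grid.values
        assert phi[cond].max() == pytest.approx(f.contact_voltage)
        assert phi[cond].min() == pytest.approx(0.0, abs=1e-12)
        assert np.isfinite(phi).all()

    def test_linearity_in_current(self):
        m = box_model()
        f1 = solve_potential(m, current=1e-3)
        f2 = solve_potential(m, current=2e-3)
        assert np.allclose(f2.grid.values, 2 * f1.grid.values, rtol=1e-10)

    def test_oracle_equivalence_homogeneous(self, small_ball_solution):
        """Solved potential vs grounded-sphere closed form outside a
        2-voxel shell around the contact."""
        f = small_ball_solution["field"]
        sigma = small_ball_solution["sigma"]
        current = small_ball_solution["current"]
        R = small_ball_solution["domain_radius"]
        k = current / (4 * np.pi * sigma)
        # the grounded shell is ~one voxel thick, so the effective Dirichlet
        # radius of the discrete domain is R - h
        r_ground = R - float(f.grid.spacing[0])
        for pt in [(6, 0, 0), (0, -8, 0), (0, 0, 10), (7, 7, 0)]:
            idx = np.round(f.grid.world_to_index(pt)).astype(int)
            pw = f.grid.index_to_world(idx)
            r = np.linalg.norm(pw)
            expected = k * (1e3 / r - 1e3 / r_ground)
            # 3% on this deliberately coarse fixture (h = 1.5 mm); the
            # 2% oracle-equivalence check runs on the refined chain in
            # the acceptance suite
            assert f.grid.values[tuple(idx)] == pytest.approx(expected, rel=0.03)

    def test_current_conservation(self, small_ball_solution):
        """Flux leaving the contact equals the injected current (exactly,
        by the scaling construction) and matches the flux into the sink
        within 0.5% (discrete conservation)."""
        m = small_ball_solution["model"]
        f = small_ball_solution["field"]
        i_out = contact_current(m, f.grid)
        assert i_out == pytest.approx(f.current, rel=1e-9)
        # flux into the sink shell, via the same face conductances
        sink_mask = small_ball_solution["sink"].mask.values
        fake = m.labels.like(np.where(sink_mask, LEAD_ACTIVE, 0).astype(np.int16))
        fake_model = TissueModel(labels=fake, conductivity=m.conductivity)
        # reuse contact_current with the sink marked active: current
        # flows *into* the sink, so the sign flips
        sigma_vol = m.sigma_volume()
        i_in = -contact_current(fake_model, f.grid, sigma=sigma_vol)
        assert i_in == pytest.approx(f.current, rel=0.005)

    def test_relabel_invariance(self):
        m1 = box_model()
        labels2 = m1.labels.like(
            np.where(m1.labels.values == GRAY_MATTER, CSF, m1.labels.values).astype(np.int16)
        )
        m2 = TissueModel(labels=labels2, conductivity={
            CSF: 0.12, LEAD_ACTIVE: 4e6, EXTERIOR: 0.0})
        f1 = solve_potential(m1, current=1e-3)
        f2 = solve_potential(m2, current=1e-3)
        assert np.allclose(f1.grid.values, f2.grid.values, atol=1e-10)

    def test_sigma_scaling_halves_impedance(self):
        f1 = solve_potential(box_model(sigma=0.12), current=1e-3)
        f2 = solve_potential(box_model(sigma=0.24), current=1e-3)
        assert f2.impedance == pytest.approx(f1.impedance / 2, rel=1e-6)
        assert f1.impedance > 0

    def test_no_conductive_path_rejected(self):
        m = box_model()
        # sever the domain with an insulating plane above the contact
        k = m.labels.shape[2] - 4
        vals = m.labels.values.copy()
        vals[:, :, : k - 10] = EXTERIOR  # isolate contact side from the sink? no:
        # simpler: insulate a full slab between contact and bottom sink
        vals = m.labels.values.copy()
        vals[:, :, 3] = EXTERIOR
        m2 = TissueModel(labels=m.labels.like(vals), conductivity=m.conductivity)
        with pytest.raises(SolverError, match="no conductive path"):
            solve_potential(m2, current=1e-3)

    def test_missing_active_label_rejected(self):
        g = VoxelGrid.from_bounds((0, 0, 0), (5, 5, 5), 1.0, dtype=np.int16,
                                  fill=GRAY_MATTER)
        m = TissueModel(labels=g, conductivity={GRAY_MATTER: 0.1})
        with pytest.raises(SolverError, match="active label"):
            solve_potential(m, current=1e-3)

    def test_zero_current_impedance_rejected(self):
        f = solve_potential(box_model(), current=1e-3)
        f.current = 0.0
        with pytest.raises(ValueError, match="zero"):
            compute_impedance(f)

    def test_residual_below_tolerance(self, small_ball_solution):
        assert small_ball_solution["field"].residual <= 1e-7


class TestSphereImpedance:
    def test_isolated_sphere_spreading_resistance(self):
        """R within 5% of (1/4 pi sigma) (1/a - 1/R_dom) for a ball contact."""
        sigma, a, R = 0.13533, 3.0, 35.0
        h = 0.5
        half = R + 2 * h
        grid = VoxelGrid.from_bounds((-half,) * 3, (half,) * 3, h,
                                     dtype=np.int16, fill=EXTERIOR)
        model = sphere_contact_phantom(grid, R, a, sigma)
        f = solve_potential(model, current=1e-3, sink=sphere_sink(grid, R))
        expected = (1 / (4 * np.pi * sigma)) * (1e3 / a - 1e3 / R)
        assert f.impedance == pytest.approx(expected, rel=0.05)


class TestRefineLocal:
    def test_noop_refinement_preserves_field(self, small_ball_solution):
        m = small_ball_solution["model"]
        f = small_ball_solution["field"]
        h = float(f.grid.spacing[0])
        refined, _ = refine_local(m, f, (0, 0, 0), box_size=16.0, fine_spacing=h)
        # compare on the refined lattice (a subgrid of the coarse one)
        idx = np.round(f.grid.world_to_index(refined.grid.origin)).astype(int)
        sl = tuple(slice(i, i + s) for i, s in zip(idx, refined.grid.shape))
        coarse_patch = f.grid.values[sl]
        cond = refined.conductive.values
        assert np.allclose(refined.grid.values[cond], coarse_patch[cond],
                           rtol=5e-3, atol=1e-4)

    def test_box_outside_domain_rejected(self, small_ball_solution):
        with pytest.raises(ValueError, match="box"):
            refine_local(small_ball_solution["model"],
                         small_ball_solution["field"],
                         (30, 0, 0), box_size=20.0, fine_spacing=0.5)

    def test_fine_spacing_coarser_than_grid_rejected(self, small_ball_solution):
        with pytest.raises(ValueError, match="fine_spacing"):
            refine_local(small_ball_solution["model"],
                         small_ball_solution["field"],
                         (0, 0, 0), box_size=10.0, fine_spacing=5.0)

    def test_refined_point_source_accuracy(self, small_ball_solution):
        """Refined solve matches the grounded-sphere closed form at r>=3mm."""
        m = small_ball_solution["model"]
        f = small_ball_solution["field"]
        sigma = small_ball_solution["sigma"]
        R = small_ball_solution["domain_radius"]
        a = small_ball_solution["contact_radius"]

        def rerasterize(g):
            return sphere_contact_phantom(g, R, a, sigma)

        refined, _ = refine_local(m, f, (0, 0, 0), box_size=16.0,
                                  fine_spacing=0.4, rerasterize=rerasterize)
        k = f.current / (4 * np.pi * sigma)
        for pt in [(3, 0, 0), (0, 4, 0), (0, 0, -5), (3, 3, 3)]:
            idx = np.round(refined.grid.world_to_index(pt)).astype(int)
            pw = refined.grid.index_to_world(idx)
            r = np.linalg.norm(pw)
            expected = k * (1e3 / r - 1e3 / R)
            assert refined.grid.values[tuple(idx)] == pytest.approx(expected, rel=0.02)

    def test_impedance_converges_under_refinement(self, ring_lead_solution):
        """Refined ring-contact impedance decreases monotonically toward a
        converged value as the local spacing halves."""
        m = ring_lead_solution["model"]
        f = ring_lead_solution["field"]
        rr = ring_lead_solution["rerasterize"]
        center = ring_lead_solution["geom"].contact_centroid(1)
        imps = []
        for h in (0.8, 0.4, 0.2):
            refined, _ = refine_local(m, f, center, box_size=16.0,
                                      fine_spacing=h, rerasterize=rr)
            imps.append(refined.impedance)
        assert imps[0] > imps[1] > imps[2]
        # successive changes shrink: approaching a converged value
        assert abs(imps[2] - imps[1]) < abs(imps[1] - imps[0])

    def test_boundary_consistency(self, small_ball_solution):
        """Fine and coarse solutions agree on the box boundary shell."""
        m = small_ball_solution["model"]
        f = small_ball_solution["field"]
        refined, _ = refine_local(m, f, (0, 0, 0), box_size=16.0, fine_spacing=0.5)
        edge = np.zeros(refined.grid.shape, dtype=bool)
        for ax in range(3):
            sl = [slice(None)] * 3
            sl[ax] = 0
            edge[tuple(sl)] = True
            sl[ax] = -1
            edge[tuple(sl)] = True
        from dbsvta.field_solver import _trilinear

        coarse_vals = _trilinear(f.grid, refined.grid)
        num = refined.grid.values[edge]
        ref = coarse_vals[edge]
        scale = np.abs(ref).max()
        assert np.abs(num - ref).max() <= 0.05 * scale
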