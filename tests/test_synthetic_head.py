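import numpy as np
import pytest
import yaml

from dbsvta.grid import VoxelGrid
from dbsvta.lead_model import fit_trajectory
from dbsvta.model import (
    CSF,
    GRAY_MATTER,
    TISSUE_LABELS,
    WHITE_MATTER,
)
from dbsvta.synthetic_head import (
    Compartment,
    PatientRecord,
    PhantomSpec,
    build_head_phantom,
    build_target_nucleus,
    default_phantom_spec,
    default_trajectory,
    make_artifact_volume,
    patient_fixture,
    threshold_artifact,
)


def single_compartment_spec(spacing=2.0):
    return PhantomSpec(
        compartments=[Compartment("all", "BrainGreyMatter", (0, 0, 0), (60, 60, 60))],
        conductivity={"BrainGreyMatter": 0.12},
        spacing=spacing,
        bounds_low=(-20, -20, -20),
        bounds_high=(20, 20, 20),
    )


class TestBuildHeadPhantom:
    def test_single_compartment_labels_everything(self):
        model = build_head_phantom(single_compartment_spec())
        assert (model.labels.values == GRAY_MATTER).all()

    def test_shell_volume_matches_analytic(self):
        # spherical gray shell radii 50/40 mm voxelized at 1 mm
        spec = PhantomSpec(
            compartments=[
                Compartment("outer", "BrainGreyMatter", (0, 0, 0), (50, 50, 50)),
                Compartment("inner", "BrainWhiteMatter", (0, 0, 0), (40, 40, 40)),
            ],
            conductivity={"BrainGreyMatter": 0.12, "BrainWhiteMatter": 0.058},
            spacing=1.0,
            bounds_low=(-52, -52, -52),
            bounds_high=(52, 52, 52),
        )
        model = build_head_phantom(spec)
        vol = (model.labels.values == GRAY_MATTER).sum() * model.labels.voxel_volume
        analytic = 4.0 / 3.0 * np.pi * (50.0**3 - 40.0**3)
        assert vol == pytest.approx(analytic, rel=0.02)

    def test_voxel_volume_converges_with_spacing(self):
        analytic = 4.0 / 3.0 * np.pi * 30.0**3

        def sphere_err(spacing):
            spec = PhantomSpec(
                compartments=[Compartment("s", "BrainGreyMatter", (0, 0, 0), (30, 30, 30))],
                conductivity={"BrainGreyMatter": 0.12},
                spacing=spacing,
                bounds_low=(-32, -32, -32),
                bounds_high=(32, 32, 32),
            )
            model = build_head_phantom(spec)
            vol = (model.labels.values == GRAY_MATTER).sum() * model.labels.voxel_volume
            return abs(vol - analytic) / analytic

        assert sphere_err(1.0) < sphere_err(4.0)

    def test_patient1_conductivity_table(self):
        model = build_head_phantom(default_phantom_spec(1))
        assert model.conductivity[GRAY_MATTER] == pytest.approx(0.120)
        assert model.conductivity[WHITE_MATTER] == pytest.approx(0.058)
        assert model.conductivity[CSF] == pytest.approx(1.800)

    def test_patient2_gray_matter_differs(self):
        model = build_head_phantom(default_phantom_spec(2))
        assert model.conductivity[GRAY_MATTER] == pytest.approx(0.090)

    def test_all_six_tissues_present_in_default(self):
        spec = default_phantom_spec(1)
        assert set(spec.conductivity) == {
            "AverageBody", "Skull", "BrainGreyMatter", "BrainWhiteMatter",
            "CerebroSpinalFluid", "Ventricle",
        }
        model = build_head_phantom(spec)
        present = set(np.unique(model.labels.values).tolist())
        for name in spec.conductivity:
            assert TISSUE_LABELS[name] in present

    def test_same_priority_overlap_rejected(self):
        spec = single_compartment_spec()
        spec.compartments = [
            Compartment("a", "BrainGreyMatter", (0, 0, 0), (10, 10, 10), priority=0),
            Compartment("b", "BrainWhiteMatter", (3, 0, 0), (10, 10, 10), priority=0),
        ]
        spec.conductivity["BrainWhiteMatter"] = 0.058
        with pytest.raises(ValueError, match="priority"):
            build_head_phantom(spec)

    def test_empty_compartment_warns(self):
        spec = single_compartment_spec()
        spec.compartments.append(
            Compartment("dust", "BrainWhiteMatter", (1.0, 1.0, 1.0), (0.1, 0.1, 0.1))
        )
        spec.conductivity["BrainWhiteMatter"] = 0.058
        with pytest.warns(UserWarning, match="empty"):
            build_head_phantom(spec)

    def test_deterministic(self):
        a = build_head_phantom(default_phantom_spec(1))
        b = build_head_phantom(default_phantom_spec(1))
        assert np.array_equal(a.labels.values, b.labels.values)


class TestTargetNucleus:
    def grid(self, spacing=0.5):
        return VoxelGrid.from_bounds((-8, -8, -8), (8, 8, 8), spacing)

    def test_sphere_volume(self):
        mask = build_target_nucleus((0, 0, 0), (5, 5, 5), self.grid())
        vol = mask.values.sum() * mask.voxel_volume
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * 125.0, rel=0.02)

    def test_degenerate_semi_axes_rejected(self):
        with pytest.raises(ValueError, match="semi_axes"):
            build_target_nucleus((0, 0, 0), (0, 0, 0), self.grid())

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_target_nucleus((100, 100, 100), (1, 1, 1), self.grid())

    def test_disjoint_ellipsoids_give_disjoint_masks(self):
        g = self.grid()
        a = build_target_nucleus((-4, 0, 0), (2, 2, 2), g)
        b = build_target_nucleus((4, 0, 0), (2, 2, 2), g)
        assert not (a.values & b.values).any()


class TestArtifactVolume:
    def test_noiseless_threshold_equals_cylinder(self):
        traj = default_trajectory()
        art = make_artifact_volume(traj, lead_radius=0.635, length=30.0,
                                   noise_sd=0.0, spacing=0.5)
        mask = threshold_artifact(art)
        # expected: voxel centers within the radius of the axis segment
        x, y, z = art.coordinate_mesh()
        p = np.stack([x - traj.tip[0] + 0 * y + 0 * z,
                      y - traj.tip[1] + 0 * x + 0 * z,
                      z - traj.tip[2] + 0 * x + 0 * y])
        t = np.clip(np.einsum("i...,i->...", p, traj.direction), 0.0, 30.0)
        d2 = ((p - t[None] * traj.direction[:, None, None, None]) ** 2).sum(axis=0)
        assert np.array_equal(mask.values, d2 <= 0.635**2)

    def test_seed_determinism(self):
        traj = default_trajectory()
        a = make_artifact_volume(traj, 0.635, 30.0, noise_sd=40.0, seed=7)
        b = make_artifact_volume(traj, 0.635, 30.0, noise_sd=40.0, seed=7)
        assert np.array_equal(a.values, b.values)
        c = make_artifact_volume(traj, 0.635, 30.0, noise_sd=40.0, seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_round_trip_recovers_direction(self):
        traj = default_trajectory()
        art = make_artifact_volume(traj, 0.635, 40.0, noise_sd=0.0, spacing=0.5)
        fitted = fit_trajectory(threshold_artifact(art))
        angle = np.degrees(np.arccos(np.clip(
            abs(np.dot(fitted.direction, traj.direction)), -1, 1)))
        assert angle < 1.0

    def test_explicit_grid_must_contain_trajectory(self):
        grid = VoxelGrid.from_bounds((0, 0, 0), (5, 5, 5), 1.0)
        with pytest.raises(ValueError, match="outside"):
            make_artifact_volume(default_trajectory(), 0.635, 60.0, grid=grid)


class TestPatientFixtures:
    def test_patient1_values(self):
        rec = patient_fixture(1)
        assert rec.current_a == pytest.approx(5.5e-3)
        assert rec.impedance_ohm == {"left": 926.0, "right": 926.0}
        assert (rec.ybocs_pre, rec.ybocs_post) == (31, 10)
        assert rec.pulse_width_us == 60.0
        assert rec.frequency_hz == 160.0
        assert rec.active_contact == {"left": 1, "right": 9}

    def test_patient2_values(self):
        rec = patient_fixture(2)
        assert rec.current_a == pytest.approx(5.25e-3)
        assert rec.impedance_ohm == {"left": 1262.0, "right": 1150.0}
        assert (rec.ybocs_pre, rec.ybocs_post) == (40, 24)

    def test_unknown_patient_rejected(self):
        with pytest.raises(ValueError, match="patient id"):
            patient_fixture(3)

    def test_record_validation(self):
        rec = patient_fixture(1)
        with pytest.raises(ValueError, match="current"):
            PatientRecord(**{**rec.__dict__, "current_a": -1.0})
        with pytest.raises(ValueError, match="Y-BOCS"):
            PatientRecord(**{**rec.__dict__, "ybocs_pre": 41})

    def test_json_round_trip(self, tmp_path):
        rec = patient_fixture(2)
        path = str(tmp_path / "p2.json")
        rec.to_json(path)
        assert PatientRecord.from_json(path) == rec


class TestSerialization:
    def test_phantom_spec_yaml_round_trip(self, tmp_path):
        spec = default_phantom_spec(1)
        path = str(tmp_path / "spec.yaml")
        spec.to_yaml(path)
        back = PhantomSpec.from_yaml(path)
        assert back.conductivity == spec.conductivity  # bit-exact floats
        assert back.spacing == spec.spacing
        assert [c.name for c in back.compartments] == [c.name for c in spec.compartments]

    def test_conductivity_floats_bit_exact(self, tmp_path):
        table = {"BrainGreyMatter": 0.1234567890123456, "CerebroSpinalFluid": 1.8}
        path = tmp_path / "table.yaml"
        path.write_text(yaml.safe_dump(table))
        back = yaml.safe_load(path.read_text())
        assert all(back[k] == table[k] for k in table)
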