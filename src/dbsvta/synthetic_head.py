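"""Synthetic head phantoms, target nuclei, pseudo-CT lead artifacts and
patient fixtures.

This module generates every input the downstream stages need, replacing
clinical MRI/CT segmentation with analytically defined nested compartments
so the whole pipeline is testable without imaging data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .grid import VoxelGrid
from .model import (
    AVERAGE_BODY,
    EXTERIOR,
    GRAY_MATTER,
    TISSUE_LABELS,
    TissueModel,
)

__all__ = [
    "Compartment",
    "PhantomSpec",
    "PatientRecord",
    "build_head_phantom",
    "build_target_nucleus",
    "make_artifact_volume",
    "threshold_artifact",
    "patient_fixture",
    "default_phantom_spec",
    "default_trajectory",
    "default_nucleus_params",
]

#: per-tissue conductivity (S/m) at stimulation frequencies, per patient
PATIENT_CONDUCTIVITY: dict[int, dict[str, float]] = {
    1: {
        "AverageBody": 0.400,
        "Skull": 0.300,
        "BrainGreyMatter": 0.120,
        "BrainWhiteMatter": 0.058,
        "CerebroSpinalFluid": 1.800,
        "Ventricle": 0.300,
    },
    2: {
        "AverageBody": 0.400,
        "Skull": 0.300,
        "BrainGreyMatter": 0.090,
        "BrainWhiteMatter": 0.058,
        "CerebroSpinalFluid": 1.800,
        "Ventricle": 0.300,
    },
}


@dataclass
class Compartment:
    """One phantom compartment: an ellipsoid or an axis-aligned box.

    ``semi_axes`` are ellipsoid semi-axes, or half-extents for a box.
    ``priority`` defaults to the list position (outermost-first); two
    compartments sharing an explicit priority must not overlap.
    """

    name: str
    tissue: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    shape: str = "ellipsoid"
    priority: int | None = None

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center
        ax, ay, az = self.semi_axes
        if min(ax, ay, az) <= 0:
            raise ValueError(f"compartment {self.name!r}: semi_axes must be positive")
        if self.shape == "ellipsoid":
            return (
                ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
            ) <= 1.0
        if self.shape == "box":
            return (
                (np.abs(x - cx) <= ax)
                & (np.abs(y - cy) <= ay)
                & (np.abs(z - cz) <= az)
            )
        raise ValueError(f"unknown compartment shape {self.shape!r}")


@dataclass
class PhantomSpec:
    """Specification of a head phantom: compartments (outermost-first),
    a tissue-name conductivity table, grid spacing and bounding box."""

    compartments: list[Compartment]
    conductivity: dict[str, float]
    spacing: float = 1.5
    bounds_low: tuple[float, float, float] = (-70.0, -70.0, -100.0)
    bounds_high: tuple[float, float, float] = (70.0, 70.0, 80.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, sigma in self.conductivity.items():
            if name not in TISSUE_LABELS:
                raise ValueError(f"unknown tissue name {name!r}")
            if sigma < 0:
                raise ValueError(f"negative conductivity for {name!r}")

    def label_table(self) -> dict[int, float]:
        """Label -> sigma table, including sigma=0 exterior."""
        table = {EXTERIOR: 0.0}
        for name, sigma in self.conductivity.items():
            table[TISSUE_LABELS[name]] = float(sigma)
        return table

    # -- serialization ------------------------------------------------

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PhantomSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["compartments"] = [Compartment(**c) for c in raw["compartments"]]
        for key in ("bounds_low", "bounds_high"):
            raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PatientRecord:
    """Stimulation settings, measured impedances and outcome scores."""

    patient_id: int
    active_contact: dict[str, int]  # side -> contact id
    current_a: float
    pulse_width_us: float
    frequency_hz: float
    impedance_ohm: dict[str, float]  # side -> measured impedance
    ybocs_pre: int
    ybocs_post: int

    def __post_init__(self) -> None:
        if self.current_a <= 0:
            raise ValueError("current must be positive")
        if any(z <= 0 for z in self.impedance_ohm.values()):
            raise ValueError("impedance must be positive")
        for score in (self.ybocs_pre, self.ybocs_post):
            if not (isinstance(score, (int, np.integer)) and 0 <= score <= 40):
                raise ValueError(f"Y-BOCS score must be an integer in [0, 40], got {score}")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "PatientRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


# ----------------------------------------------------------------------
# phantom construction


def build_head_phantom(spec: PhantomSpec, grid: VoxelGrid | None = None) -> TissueModel:
    """Voxelize a phantom spec into a labeled tissue model.

    Each voxel is labeled by the innermost (last-listed / highest-priority)
    compartment containing its center.  Compartments with an identical
    explicit priority must not overlap.  ``grid`` overrides the spec's
    bounding box / spacing (used to re-voxelize inside refinement boxes).
    """
    full_domain = grid is None
    if grid is None:
        grid = VoxelGrid.from_bounds(
            spec.bounds_low, spec.bounds_high, spec.spacing, dtype=np.int16, fill=EXTERIOR
        )
    else:
        grid = grid.like(np.full(grid.shape, EXTERIOR, dtype=np.int16))
    x, y, z = grid.coordinate_mesh()

    labels = grid.values
    priorities = [
        c.priority if c.priority is not None else i
        for i, c in enumerate(spec.compartments)
    ]
    order = np.argsort(np.asarray(priorities), kind="stable")
    masks: list[np.ndarray] = [None] * len(spec.compartments)  # type: ignore[list-item]
    for i, comp in enumerate(spec.compartments):
        masks[i] = comp.contains(x, y, z)
        if full_domain and not masks[i].any():
            warnings.warn(
                f"compartment {comp.name!r} is empty after voxelization", stacklevel=2
            )

    # reject overlapping compartments that claim the same priority
    for i in range(len(spec.compartments)):
        for j in range(i + 1, len(spec.compartments)):
            if priorities[i] == priorities[j] and np.any(masks[i] & masks[j]):
                raise ValueError(
                    f"compartments {spec.compartments[i].name!r} and "
                    f"{spec.compartments[j].name!r} share priority "
                    f"{priorities[i]} but overlap"
                )

    for i in order:
        comp = spec.compartments[i]
        labels[masks[i]] = TISSUE_LABELS[comp.tissue]

    return TissueModel(labels=grid, conductivity=spec.label_table())


def build_target_nucleus(
    center: np.ndarray, semi_axes: np.ndarray, grid: VoxelGrid
) -> VoxelGrid:
    """Binary mask of an ellipsoidal target nucleus on ``grid``.

    Raises if the ellipsoid captures no voxel center.
    """
    center = np.asarray(center, dtype=float)
    semi_axes = np.asarray(semi_axes, dtype=float)
    if np.any(semi_axes <= 0):
        raise ValueError(f"semi_axes must be positive, got {semi_axes}")
    x, y, z = grid.coordinate_mesh()
    mask = (
        ((x - center[0]) / semi_axes[0]) ** 2
        + ((y - center[1]) / semi_axes[1]) ** 2
        + ((z - center[2]) / semi_axes[2]) ** 2
    ) <= 1.0
    if not mask.any():
        raise ValueError("target nucleus mask is empty on this grid")
    return grid.like(mask)


# ----------------------------------------------------------------------
# pseudo-CT lead artifact

_ARTIFACT_INTENSITY = 1000.0


def make_artifact_volume(
    trajectory,
    lead_radius: float,
    length: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    grid: VoxelGrid | None = None,
    spacing: float = 0.5,
    margin: float = 8.0,
) -> VoxelGrid:
    """Hyperdense cylindrical lead artifact with additive Gaussian noise.

    Voxels within ``lead_radius`` of the axis segment from the trajectory
    tip extending ``length`` mm proximally get intensity 1000; Gaussian
    noise of standard deviation ``noise_sd`` is added everywhere.
    Deterministic for a fixed ``seed``.
    """
    tip = np.asarray(trajectory.tip, dtype=float)
    direction = np.asarray(trajectory.direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    end = tip + direction * length

    if grid is None:
        low = np.minimum(tip, end) - (lead_radius + margin)
        high = np.maximum(tip, end) + (lead_radius + margin)
        grid = VoxelGrid.from_bounds(low, high, spacing)
    else:
        grid = grid.like(np.zeros(grid.shape))
        if not (grid.contains_point(tip) and grid.contains_point(end)):
            raise ValueError("trajectory segment extends outside the grid")

    x, y, z = grid.coordinate_mesh()
    px = x - tip[0]
    py = y - tip[1]
    pz = z - tip[2]
    t = px * direction[0] + py * direction[1] + pz * direction[2]
    t = np.clip(t, 0.0, length)
    dist2 = (
        (px - t * direction[0]) ** 2
        + (py - t * direction[1]) ** 2
        + (pz - t * direction[2]) ** 2
    )
    values = np.where(dist2 <= lead_radius**2, _ARTIFACT_INTENSITY, 0.0)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)

    return grid.like(values)


def threshold_artifact(artifact: VoxelGrid, level: float | None = None) -> VoxelGrid:
    """Binarize a hyperdense artifact volume (default: half peak intensity)."""
    if level is None:
        level = _ARTIFACT_INTENSITY / 2.0
    return artifact.like(artifact.values >= level)


# ----------------------------------------------------------------------
# patient fixtures

_PATIENT_FIXTURES = {
    1: dict(
        patient_id=1,
        active_contact={"left": 1, "right": 9},
        current_a=5.5e-3,
        pulse_width_us=60.0,
        frequency_hz=160.0,
        impedance_ohm={"left": 926.0, "right": 926.0},
        ybocs_pre=31,
        ybocs_post=10,
    ),
    2: dict(
        patient_id=2,
        active_contact={"left": 1, "right": 9},
        current_a=5.25e-3,
        pulse_width_us=60.0,
        frequency_hz=160.0,
        impedance_ohm={"left": 1262.0, "right": 1150.0},
        ybocs_pre=40,
        ybocs_post=24,
    ),
}


def patient_fixture(patient_id: int) -> PatientRecord:
    """Clinical record for patient 1 or 2 (stimulation settings, measured
    impedances, pre/post outcome scores)."""
    try:
        raw = _PATIENT_FIXTURES[patient_id]
    except KeyError:
        raise ValueError(f"unknown patient id {patient_id!r}; valid ids are 1 and 2")
    return PatientRecord(**{k: (dict(v) if isinstance(v, dict) else v) for k, v in raw.items()})


# ----------------------------------------------------------------------
# study defaults: a desk-scale head phantom with a deep gray target region


def default_phantom_spec(patient_id: int = 1, spacing: float = 1.5) -> PhantomSpec:
    """Nested-ellipsoid head over a torso slab, all six standard tissues.

    The innermost 'deep gray' ellipsoid models basal-ganglia gray matter
    so the lead tip region is gray matter, as for a ventral-striatum target.
    """
    comps = [
        Compartment("torso_slab", "AverageBody", (0, 0, -80), (70, 70, 20), shape="box"),
        Compartment("scalp", "AverageBody", (0, 0, 0), (66, 66, 76)),
        Compartment("skull", "Skull", (0, 0, 0), (60, 60, 70)),
        Compartment("csf", "CerebroSpinalFluid", (0, 0, 0), (56, 56, 66)),
        Compartment("gray", "BrainGreyMatter", (0, 0, 0), (52, 52, 62)),
        Compartment("white", "BrainWhiteMatter", (0, 0, 0), (44, 44, 52)),
        Compartment("deep_gray", "BrainGreyMatter", (8, 10, -12), (16, 14, 16)),
        Compartment("ventricle", "Ventricle", (0, 0, 14), (10, 14, 12)),
    ]
    return PhantomSpec(
        compartments=comps,
        conductivity=dict(PATIENT_CONDUCTIVITY[patient_id]),
        spacing=spacing,
    )


def default_trajectory(side: str = "left"):
    """Oblique implant trajectory ending in the deep gray ellipsoid.

    The right-side trajectory is the left one mirrored in x.
    """
    from .lead_model import Trajectory

    direction = np.array([0.30, 0.20, 0.93])
    tip = np.array([6.0, 8.0, -10.0])
    if side == "right":
        direction = direction * np.array([-1.0, 1.0, 1.0])
        tip = tip * np.array([-1.0, 1.0, 1.0])
    elif side != "left":
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return Trajectory(tip=tip, direction=direction / np.linalg.norm(direction))


#: lateral nucleus offset (mm) from the lead tip, per patient; the larger
#: offset yields the smaller activation overlap, so the two synthetic
#: patients reproduce the study's overlap ordering (patient 1 > patient 2)
_NUCLEUS_LATERAL_OFFSET = {1: 6.5, 2: 8.0}


def default_nucleus_params(
    patient_id: int = 1, side: str = "left"
) -> tuple[np.ndarray, np.ndarray]:
    """(center, semi_axes) of a ~480 mm^3 target nucleus a few mm lateral
    to the lead tip of ``side``.  Placement differs between the two
    synthetic patients so their overlap fractions differ."""
    offset = _NUCLEUS_LATERAL_OFFSET[patient_id]
    tip = default_trajectory(side).tip
    lateral = np.array([offset, 0.0, 0.0])
    if side == "right":
        lateral = -lateral
    return tip + lateral + np.array([0.0, 0.0, -1.0]), np.array([5.2, 4.6, 4.8])
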