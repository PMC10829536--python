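"""Directional DBS lead: axis reconstruction from an artifact mask,
8-contact geometry construction, and rasterization into a tissue model.

The lead has, distal to proximal, one ring contact, two levels of three
radially segmented contacts, and one ring contact.  Contact ids are
1..8 (left lead) or 9..16 (right, ``id_offset=8``); id 1 / 9 is the
distal ring and starts exactly at the trajectory tip.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .grid import VoxelGrid
from .model import (
    CONDUCTOR_SIGMA,
    LEAD_ACTIVE,
    LEAD_CONTACT,
    LEAD_SHAFT,
    TissueModel,
)

__all__ = [
    "Trajectory",
    "LeadSpec",
    "Contact",
    "LeadGeometry",
    "fit_trajectory",
    "build_lead",
    "rasterize_lead",
]


@dataclass
class Trajectory:
    """Lead axis: distal tip point (mm) and unit direction pointing proximally."""

    tip: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.tip = np.asarray(self.tip, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"direction must be a unit vector, |d| = {norm}")


@dataclass
class LeadSpec:
    """Dimensions and electrical properties of a directional lead."""

    contact_height: float = 1.5
    radius: float = 0.635
    spacing: float = 1.5  # edge-to-edge inter-level gap
    rows: tuple[str, ...] = ("ring", "segmented", "segmented", "ring")
    segment_arc_deg: float = 100.0
    segment_gap_deg: float = 20.0
    shaft_length: float = 60.0
    shaft_sigma: float = 0.0
    contact_sigma: float = CONDUCTOR_SIGMA

    def __post_init__(self) -> None:
        for name in (
            "contact_height",
            "radius",
            "spacing",
            "segment_arc_deg",
            "segment_gap_deg",
            "shaft_length",
            "shaft_sigma",
            "contact_sigma",
        ):
            setattr(self, name, float(getattr(self, name)))
        if min(self.contact_height, self.radius, self.spacing) <= 0:
            raise ValueError("contact height, radius and spacing must be positive")
        if tuple(self.rows) != ("ring", "segmented", "segmented", "ring"):
            raise ValueError("rows must be (ring, segmented, segmented, ring)")
        if abs(3 * (self.segment_arc_deg + self.segment_gap_deg) - 360.0) > 1e-9:
            raise ValueError("3 * (arc + gap) must equal 360 degrees")

    @property
    def n_contacts(self) -> int:
        return sum(1 if r == "ring" else 3 for r in self.rows)

    @property
    def array_span(self) -> float:
        """Axial extent of the contact array from the distal tip, mm."""
        n = len(self.rows)
        return n * self.contact_height + (n - 1) * self.spacing

    @classmethod
    def from_yaml(cls, path: str) -> "LeadSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "rows" in raw:
            raw["rows"] = tuple(raw["rows"])
        return cls(**raw)

    @classmethod
    def abbott_6172(cls) -> "LeadSpec":
        """The packaged default directional-lead spec."""
        ref = importlib.resources.files("dbsvta").joinpath("data/abbott_6172.yaml")
        raw = yaml.safe_load(ref.read_text())
        raw["rows"] = tuple(raw["rows"])
        return cls(**raw)


@dataclass
class Contact:
    """One contact solid: axial interval along the axis (mm from tip) and,
    for segmented contacts, an angular sector (degrees) in the lead frame."""

    contact_id: int
    level: int
    kind: str  # "ring" | "segment"
    axial: tuple[float, float]
    sector_deg: tuple[float, float] | None = None


@dataclass
class LeadGeometry:
    """Placed lead: trajectory, spec, contact solids and lead-frame basis."""

    trajectory: Trajectory
    spec: LeadSpec
    contacts: list[Contact]
    frame_u: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    frame_v: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def contact_ids(self) -> list[int]:
        return [c.contact_id for c in self.contacts]

    def contact(self, contact_id: int) -> Contact:
        for c in self.contacts:
            if c.contact_id == contact_id:
                return c
        raise KeyError(f"contact id {contact_id} not in geometry {self.contact_ids}")

    def contact_centroid(self, contact_id: int) -> np.ndarray:
        """World centroid of a contact solid (on the axis for rings,
        mid-sector on the surface for segments)."""
        c = self.contact(contact_id)
        s = 0.5 * (c.axial[0] + c.axial[1])
        center = self.trajectory.tip + s * self.trajectory.direction
        if c.sector_deg is not None:
            mid = np.deg2rad(0.5 * (c.sector_deg[0] + c.sector_deg[1]))
            center = center + self.spec.radius * (
                np.cos(mid) * self.frame_u + np.sin(mid) * self.frame_v
            )
        return center


# ----------------------------------------------------------------------
# trajectory reconstruction


def fit_trajectory(
    artifact_mask: VoxelGrid,
    distal: str = "low_z",
    min_anisotropy: float = 3.0,
) -> Trajectory:
    """Total-least-squares line through an elongated artifact mask.

    The direction is the principal axis of the mask voxel-center
    coordinates; the tip is the extreme mask point projected onto the
    axis at the distal end (``distal='low_z'``: the end deeper in the
    head, smaller z).  The returned direction points tip -> proximal.
    """
    mask = artifact_mask.values.astype(bool)
    if not mask.any():
        raise ValueError("artifact mask is empty")
    idx = np.argwhere(mask).astype(float)
    coords = artifact_mask.origin + idx * artifact_mask.spacing
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    # principal axes via SVD; singular values ~ principal extents
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] == 0:
        anisotropy = np.inf
    else:
        anisotropy = svals[0] / svals[1]
    if anisotropy < min_anisotropy:
        raise ValueError(
            f"artifact mask fails the anisotropy check: principal-extent ratio "
            f"{anisotropy:.2f} < {min_anisotropy} (mask is not elongated)"
        )
    axis = vt[0]
    t = centered @ axis
    end_a = centroid + t.min() * axis
    end_b = centroid + t.max() * axis
    if distal == "low_z":
        tip, other = (end_a, end_b) if end_a[2] <= end_b[2] else (end_b, end_a)
    elif distal == "high_z":
        tip, other = (end_a, end_b) if end_a[2] >= end_b[2] else (end_b, end_a)
    else:
        raise ValueError("distal must be 'low_z' or 'high_z'")
    direction = other - tip
    direction = direction / np.linalg.norm(direction)
    return Trajectory(tip=tip, direction=direction)


# ----------------------------------------------------------------------
# geometry construction


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(axis, helper)) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    u = np.cross(helper, axis)
    u = u / np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def build_lead(traj: Trajectory, spec: LeadSpec, id_offset: int = 0) -> LeadGeometry:
    """Place the 8-contact array along the trajectory, distal to proximal.

    Level ``i`` occupies axial interval
    ``[i*(height+spacing), i*(height+spacing) + height]`` from the tip, so
    the array spans ``4*height + 3*spacing`` mm.
    """
    contacts: list[Contact] = []
    next_id = 1 + id_offset
    pitch = spec.contact_height + spec.spacing
    half_arc = spec.segment_arc_deg / 2.0
    for level, kind in enumerate(spec.rows):
        s0 = level * pitch
        axial = (s0, s0 + spec.contact_height)
        if kind == "ring":
            contacts.append(Contact(next_id, level, "ring", axial))
            next_id += 1
        else:
            for k in range(3):
                center_deg = 120.0 * k
                sector = (center_deg - half_arc, center_deg + half_arc)
                contacts.append(Contact(next_id, level, "segment", axial, sector))
                next_id += 1
    u, v = _orthonormal_frame(traj.direction)
    return LeadGeometry(trajectory=traj, spec=spec, contacts=contacts, frame_u=u, frame_v=v)


# ----------------------------------------------------------------------
# rasterization


def _cylinder_coords(geom: LeadGeometry, grid: VoxelGrid):
    """Axial distance from tip, radial distance to axis, and angle (deg)
    in the lead frame, for every voxel center."""
    x, y, z = grid.coordinate_mesh()
    tip = geom.trajectory.tip
    d = geom.trajectory.direction
    px, py, pz = x - tip[0], y - tip[1], z - tip[2]
    t = px * d[0] + py * d[1] + pz * d[2]
    rx = px - t * d[0]
    ry = py - t * d[1]
    rz = pz - t * d[2]
    radial = np.sqrt(rx * rx + ry * ry + rz * rz)
    cu = rx * geom.frame_u[0] + ry * geom.frame_u[1] + rz * geom.frame_u[2]
    cv = rx * geom.frame_v[0] + ry * geom.frame_v[1] + rz * geom.frame_v[2]
    angle = np.degrees(np.arctan2(cv, cu))
    return t, radial, angle


def capture_radius(spec: LeadSpec, grid: VoxelGrid) -> float:
    """Effective rasterization radius.

    On grids coarser than the physical lead radius the cylinder may miss
    every voxel center, so the radius is widened to 0.75 of the largest
    voxel edge — just enough to guarantee a connected voxel chain.
    """
    return max(spec.radius, 0.75 * float(grid.spacing.max()))


def _contact_masks(
    geom: LeadGeometry, grid: VoxelGrid
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """(shaft cylinder mask, per-contact shell masks) on ``grid``."""
    spec = geom.spec
    t, radial, angle = _cylinder_coords(geom, grid)
    r_eff = capture_radius(spec, grid)
    shell = float(grid.spacing.max())  # one-voxel-thick contact shell
    cylinder = (t >= 0.0) & (t <= spec.shaft_length) & (radial <= r_eff)

    masks: dict[int, np.ndarray] = {}
    surface = radial >= max(r_eff - shell, 0.0)
    for c in geom.contacts:
        m = cylinder & surface & (t >= c.axial[0]) & (t <= c.axial[1])
        if c.sector_deg is not None:
            start, stop = c.sector_deg
            width = stop - start
            m = m & (np.mod(angle - start, 360.0) <= width)
        masks[c.contact_id] = m
    return cylinder, masks


def rasterize_lead(
    geom: LeadGeometry, model: TissueModel, active_id: int, allow_partial: bool = False
) -> TissueModel:
    """Stamp the lead into a tissue model.

    The shaft cylinder becomes insulator (sigma = 0), non-active contact
    shells become conductor (sigma = 4e6 S/m), and the active contact gets
    a dedicated source label.  All other voxels keep their tissue labels.
    Idempotent.  ``allow_partial`` permits the lead to extend beyond the
    grid (used when re-rasterizing inside a refinement box).
    """
    if active_id not in geom.contact_ids:
        raise KeyError(
            f"active contact {active_id} not in geometry (ids {geom.contact_ids})"
        )
    grid = model.labels
    if not allow_partial:
        tip = geom.trajectory.tip
        proximal_end = tip + geom.spec.shaft_length * geom.trajectory.direction
        for pt, name in ((tip, "tip"), (proximal_end, "proximal shaft end")):
            if not grid.contains_point(pt):
                raise ValueError(f"lead exits the model grid at the {name}: {pt}")

    cylinder, masks = _contact_masks(geom, grid)
    labels = grid.values.copy()
    labels[cylinder] = LEAD_SHAFT
    for cid, m in masks.items():
        labels[m] = LEAD_ACTIVE if cid == active_id else LEAD_CONTACT

    table = dict(model.conductivity)
    table[LEAD_SHAFT] = geom.spec.shaft_sigma
    table[LEAD_CONTACT] = geom.spec.contact_sigma
    table[LEAD_ACTIVE] = geom.spec.contact_sigma
    return TissueModel(labels=grid.like(labels), conductivity=table)


def contact_id_volume(geom: LeadGeometry, grid: VoxelGrid) -> VoxelGrid:
    """Integer volume of contact ids (0 elsewhere) for visual inspection."""
    _, masks = _contact_masks(geom, grid)
    out = np.zeros(grid.shape, dtype=np.int16)
    for cid, m in masks.items():
        out[m] = cid
    return grid.like(out)
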