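"""Closed-form oracle harnesses: homogeneous phantoms with analytic answers.

These builders back the verification suite and the acceptance report:
an isolated spherical contact in a homogeneous conductive ball has
closed-form potential, spreading resistance and activation volume, so
every pipeline stage can be checked against exact numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field_solver import PotentialField, SinkSpec, refine_local, solve_potential
from .grid import VoxelGrid
from .model import CONDUCTOR_SIGMA, EXTERIOR, GRAY_MATTER, LEAD_ACTIVE, TissueModel
from .vta_metric import (
    VTAConfig,
    hessian_primary_eigenvalue,
    sample_grid,
    threshold_vta,
)

__all__ = [
    "sphere_contact_phantom",
    "sphere_sink",
    "point_source_chain",
    "point_source_vta_volume",
    "spreading_resistance_sphere",
    "sigma_from_sphere_resistance",
    "closed_form_vta_volume",
    "PointSourceChain",
]


def spreading_resistance_sphere(sigma: float, radius_mm: float) -> float:
    """Spreading resistance of an isolated sphere electrode, 1/(4 pi sigma a)."""
    return 1.0 / (4.0 * np.pi * sigma * radius_mm * 1e-3)


def sigma_from_sphere_resistance(resistance: float, radius_mm: float) -> float:
    """Invert the isolated-sphere spreading resistance for conductivity."""
    return 1.0 / (4.0 * np.pi * resistance * radius_mm * 1e-3)


def closed_form_vta_volume(current: float, sigma: float, threshold_v_per_m2: float) -> float:
    """Activation volume (mm^3) of an ideal point source: 2 I / (3 sigma T).

    The primary Hessian eigenvalue of ``k/r`` is ``2k/r^3``, so the
    activated ball has radius ``(2k/T)^(1/3)``.
    """
    return 2.0 * current / (3.0 * sigma * threshold_v_per_m2) * 1e9


def sphere_contact_phantom(
    grid: VoxelGrid,
    domain_radius: float,
    contact_radius: float,
    sigma: float = 0.12,
    tissue_label: int = GRAY_MATTER,
    center: np.ndarray | None = None,
) -> TissueModel:
    """Homogeneous conductive ball with a spherical contact at its center."""
    cx, cy, cz = (0.0, 0.0, 0.0) if center is None else center
    x, y, z = grid.coordinate_mesh()
    r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
    labels = np.full(grid.shape, EXTERIOR, dtype=np.int16)
    labels[r <= domain_radius] = tissue_label
    labels[r <= contact_radius] = LEAD_ACTIVE
    return TissueModel(
        labels=grid.like(labels),
        conductivity={
            EXTERIOR: 0.0,
            tissue_label: sigma,
            LEAD_ACTIVE: CONDUCTOR_SIGMA,
        },
    )


def sphere_sink(grid: VoxelGrid, domain_radius: float, thickness_voxels: float = 1.5) -> SinkSpec:
    """Grounded shell on the surface of the conductive ball."""
    x, y, z = grid.coordinate_mesh()
    r = np.sqrt(x * x + y * y + z * z)
    h = float(grid.spacing.max())
    shell = (r <= domain_radius) & (r > domain_radius - thickness_voxels * h)
    return SinkSpec(mask=grid.like(shell))


@dataclass
class PointSourceChain:
    """Solved homogeneous sphere at three nested resolutions."""

    coarse: PotentialField
    mid: PotentialField
    fine: PotentialField
    fine_model: TissueModel
    sigma: float
    current: float
    domain_radius: float
    contact_radius: float


def point_source_chain(
    current: float = 5.5e-3,
    sigma: float = 0.12,
    domain_radius: float = 300.0,
    coarse_spacing: float = 4.0,
    mid_box: float = 60.0,
    mid_spacing: float = 1.0,
    fine_box: float = 20.0,
    fine_spacing: float = 0.25,
    contact_radius: float = 1.0,
    tolerance: float = 1e-8,
) -> PointSourceChain:
    """Solve the small-spherical-contact problem on a large homogeneous
    ball, then refine twice around the source.

    The domain is large enough that the grounded-shell correction
    ``-k/R_domain`` stays small against ``k/r`` at millimetre radii, so
    the refined field approximates the free-space point source.
    """
    half = domain_radius + 2 * coarse_spacing
    grid = VoxelGrid.from_bounds((-half,) * 3, (half,) * 3, coarse_spacing,
                                 dtype=np.int16, fill=EXTERIOR)
    # on the coarse lattice the physical contact may miss every voxel
    # center; use a capture ball there, the true radius on refined levels
    coarse_contact = max(contact_radius, 0.8 * coarse_spacing)
    model = sphere_contact_phantom(grid, domain_radius, coarse_contact, sigma)
    sink = sphere_sink(grid, domain_radius)
    coarse = solve_potential(model, current=current, sink=sink, tolerance=tolerance)

    def rerasterize(g: VoxelGrid) -> TissueModel:
        return sphere_contact_phantom(g, domain_radius, contact_radius, sigma)

    mid, mid_model = refine_local(
        model, coarse, (0.0, 0.0, 0.0), box_size=mid_box,
        fine_spacing=mid_spacing, rerasterize=rerasterize, tolerance=tolerance,
    )
    fine, fine_model = refine_local(
        mid_model, mid, (0.0, 0.0, 0.0), box_size=fine_box,
        fine_spacing=fine_spacing, rerasterize=rerasterize, tolerance=tolerance,
    )
    return PointSourceChain(
        coarse=coarse, mid=mid, fine=fine, fine_model=fine_model,
        sigma=sigma, current=current, domain_radius=domain_radius,
        contact_radius=contact_radius,
    )


def point_source_vta_volume(
    chain: PointSourceChain,
    cfg: VTAConfig | None = None,
    exclusion_radius: float = 1.5,
) -> float:
    """Activation volume (mm^3) from the refined solve, with the
    near-contact exclusion ball added back analytically (the exclusion
    ball lies entirely inside the activated region for these settings)."""
    cfg = cfg or VTAConfig(box_mm=16.0, spacing_mm=0.1)
    # offset the box half a voxel so no sample lands exactly on the center
    center = np.full(3, cfg.spacing_mm / 2.0)
    phi = sample_grid(chain.fine, cfg, center)
    eig = hessian_primary_eigenvalue(phi)
    x, y, z = phi.coordinate_mesh()
    r = np.sqrt(x * x + y * y + z * z)
    exclusion = phi.like(r <= exclusion_radius)
    vta = threshold_vta(eig, cfg, exclusion)
    return vta.volume_mm3 + 4.0 / 3.0 * np.pi * exclusion_radius**3
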