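"""Volume of tissue activated from the Hessian of the potential.

The potential is resampled onto a fine regular cube around the active
contact, the 3x3 matrix of second spatial derivatives is formed at every
node by central differences, and the activation region is the set of nodes
whose algebraically largest ("primary") eigenvalue meets the activation
threshold.  The threshold is entered in V/cm^2 as printed on programming
tables and converted to SI V/m^2 by a factor of exactly 1e4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .field_solver import PotentialField, _resample_nearest, _sample_indices
from .grid import VoxelGrid
from .model import LEAD_ACTIVE, LEAD_CONTACT, LEAD_SHAFT, TissueModel

__all__ = [
    "VTAConfig",
    "EigenField",
    "VTAResult",
    "sample_grid",
    "hessian_primary_eigenvalue",
    "threshold_vta",
    "lead_exclusion_mask",
    "compute_vta",
    "V_PER_CM2_TO_V_PER_M2",
]

#: exact unit conversion for the activation threshold
V_PER_CM2_TO_V_PER_M2 = 1.0e4

_EIG_CHUNK = 1 << 19  # nodes per eigvalsh batch, bounds peak memory


@dataclass
class VTAConfig:
    """Fine-grid and threshold settings for the activation volume."""

    box_mm: float = 20.0
    spacing_mm: float = 0.1
    threshold_v_per_cm2: float = 26.6
    exclusion_shell: int = 2  # fine voxels dilated around lead voxels

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0 or self.box_mm <= 0:
            raise ValueError("box size and spacing must be positive")
        if self.threshold_v_per_cm2 <= 0:
            raise ValueError("threshold must be positive")

    @property
    def threshold_v_per_m2(self) -> float:
        return self.threshold_v_per_cm2 * V_PER_CM2_TO_V_PER_M2


@dataclass
class EigenField:
    """Primary Hessian eigenvalue per node (V/m^2) with a validity mask
    (the one-voxel finite-difference border is invalid)."""

    lambda1: VoxelGrid
    valid: VoxelGrid
    eigenvectors: np.ndarray | None = field(repr=False, default=None)


@dataclass
class VTAResult:
    """Binary activation mask and its volume."""

    mask: VoxelGrid
    volume_mm3: float
    threshold_v_per_cm2: float
    excluded: VoxelGrid

    def __post_init__(self) -> None:
        expected = float(self.mask.values.sum()) * self.mask.voxel_volume
        if not np.isclose(self.volume_mm3, expected):
            raise ValueError("volume does not match mask count x voxel volume")


def sample_grid(
    fieldv: PotentialField, cfg: VTAConfig, center: np.ndarray, order: int = 3
) -> VoxelGrid:
    """Resample the potential onto a cube of ``cfg.box_mm`` around
    ``center`` at ``cfg.spacing_mm``.

    Interpolation is a cubic B-spline by default: it reproduces affine and
    quadratic fields exactly and — unlike trilinear interpolation — has
    continuous second derivatives, which the downstream Hessian needs when
    the sampling grid is finer than the solved grid.  ``order=1`` gives
    plain trilinear interpolation.
    """
    center = np.asarray(center, dtype=float)
    half = cfg.box_mm / 2.0
    src = fieldv.grid
    lo_idx = src.world_to_index(center - half)
    hi_idx = src.world_to_index(center + half)
    if np.any(lo_idx < 0) or np.any(hi_idx > np.array(src.shape) - 1):
        raise ValueError("VTA sampling box exceeds the solved field's grid")
    n = int(round(cfg.box_mm / cfg.spacing_mm)) + 1
    dst = VoxelGrid(
        origin=center - half,
        spacing=np.full(3, cfg.spacing_mm),
        values=np.zeros((n, n, n)),
    )
    vals = ndimage.map_coordinates(
        src.values.astype(float),
        _sample_indices(src, dst),
        order=order,
        mode="nearest",
    ).reshape(dst.shape)
    return dst.like(vals)


def hessian_primary_eigenvalue(
    phi: VoxelGrid, compute_eigenvectors: bool = False
) -> EigenField:
    """Largest eigenvalue of the Hessian of phi at every interior node.

    Pure second derivatives use the standard three-point stencil, mixed
    partials the four-point cross stencil; units are V/m^2 (grid spacing
    is mm).  Requires an isotropic grid at least 3 voxels wide per axis.
    """
    if min(phi.shape) < 3:
        raise ValueError("grid must be at least 3 voxels wide on every axis")
    if not phi.is_isotropic:
        raise ValueError(
            f"Hessian requires uniform (isotropic) spacing, got {phi.spacing}"
        )
    h = float(phi.spacing[0]) * 1e-3  # m
    v = np.asarray(phi.values, dtype=float)

    c = (slice(1, -1),)  # interior slice helper
    core = (slice(1, -1), slice(1, -1), slice(1, -1))
    shape_in = tuple(s - 2 for s in phi.shape)

    def pure(axis: int) -> np.ndarray:
        sl_p = [slice(1, -1)] * 3
        sl_m = [slice(1, -1)] * 3
        sl_p[axis] = slice(2, None)
        sl_m[axis] = slice(None, -2)
        return (v[tuple(sl_p)] - 2.0 * v[core] + v[tuple(sl_m)]) / h**2

    def mixed(a: int, b: int) -> np.ndarray:
        sl = {}
        for sa in (1, -1):
            for sb in (1, -1):
                s = [slice(1, -1)] * 3
                s[a] = slice(2, None) if sa == 1 else slice(None, -2)
                s[b] = slice(2, None) if sb == 1 else slice(None, -2)
                sl[(sa, sb)] = v[tuple(s)]
        return (sl[(1, 1)] - sl[(1, -1)] - sl[(-1, 1)] + sl[(-1, -1)]) / (4.0 * h**2)

    hxx, hyy, hzz = pure(0), pure(1), pure(2)
    hxy, hxz, hyz = mixed(0, 1), mixed(0, 2), mixed(1, 2)

    n_nodes = int(np.prod(shape_in))
    hess = np.empty((n_nodes, 3, 3))
    hess[:, 0, 0] = hxx.ravel()
    hess[:, 1, 1] = hyy.ravel()
    hess[:, 2, 2] = hzz.ravel()
    hess[:, 0, 1] = hess[:, 1, 0] = hxy.ravel()
    hess[:, 0, 2] = hess[:, 2, 0] = hxz.ravel()
    hess[:, 1, 2] = hess[:, 2, 1] = hyz.ravel()

    lam = np.empty(n_nodes)
    vecs = np.empty((n_nodes, 3)) if compute_eigenvectors else None
    for start in range(0, n_nodes, _EIG_CHUNK):
        block = hess[start : start + _EIG_CHUNK]
        if compute_eigenvectors:
            w, q = np.linalg.eigh(block)
            lam[start : start + _EIG_CHUNK] = w[:, -1]
            vecs[start : start + _EIG_CHUNK] = q[:, :, -1]  # type: ignore[index]
        else:
            w = np.linalg.eigvalsh(block)
            lam[start : start + _EIG_CHUNK] = w[:, -1]

    lam_full = np.full(phi.shape, np.nan)
    lam_full[core] = lam.reshape(shape_in)
    valid = np.zeros(phi.shape, dtype=bool)
    valid[core] = True

    eigvec_full = None
    if compute_eigenvectors:
        eigvec_full = np.full(phi.shape + (3,), np.nan)
        eigvec_full[core] = vecs.reshape(shape_in + (3,))  # type: ignore[union-attr]

    return EigenField(
        lambda1=phi.like(lam_full), valid=phi.like(valid), eigenvectors=eigvec_full
    )


def threshold_vta(
    eig: EigenField, cfg: VTAConfig, exclusion: VoxelGrid | None = None
) -> VTAResult:
    """Activation mask: primary eigenvalue >= threshold, outside the
    exclusion region and the invalid finite-difference border."""
    grid = eig.lambda1
    if exclusion is None:
        exclusion = grid.like(np.zeros(grid.shape, dtype=bool))
    if not exclusion.same_lattice(grid):
        raise ValueError("exclusion mask is not on the eigenvalue grid")
    lam = grid.values
    with np.errstate(invalid="ignore"):
        mask = (
            (lam >= cfg.threshold_v_per_m2)
            & eig.valid.values.astype(bool)
            & ~exclusion.values.astype(bool)
        )
    volume = float(mask.sum()) * grid.voxel_volume
    return VTAResult(
        mask=grid.like(mask),
        volume_mm3=volume,
        threshold_v_per_cm2=cfg.threshold_v_per_cm2,
        excluded=exclusion,
    )


def lead_exclusion_mask(
    model: TissueModel, grid: VoxelGrid, shell: int = 2
) -> VoxelGrid:
    """Lead body (shaft + contacts) resampled to ``grid`` and dilated by
    ``shell`` voxels; finite differences across the metal/insulator
    boundary are meaningless and are removed before thresholding."""
    lead = np.isin(model.labels.values, (LEAD_SHAFT, LEAD_CONTACT, LEAD_ACTIVE))
    on_fine = _resample_nearest(model.labels.like(lead), grid).astype(bool)
    if shell > 0 and on_fine.any():
        on_fine = ndimage.binary_dilation(on_fine, iterations=shell)
    return grid.like(on_fine)


def compute_vta(
    fieldv: PotentialField,
    model: TissueModel,
    cfg: VTAConfig,
    center: np.ndarray,
) -> VTAResult:
    """sample -> Hessian -> exclusion -> threshold, in one call."""
    phi = sample_grid(fieldv, cfg, center)
    eig = hessian_primary_eigenvalue(phi)
    exclusion = lead_exclusion_mask(model, phi, shell=cfg.exclusion_shell)
    return threshold_vta(eig, cfg, exclusion)
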