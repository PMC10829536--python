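"""Quasi-static volume-conductor solver.

Solves ``div(sigma grad phi) = 0`` on a voxelized heterogeneous model with
a finite-volume 7-point stencil and harmonic-mean face conductivities.
Excitation is monopolar: the active contact is held at 1 V (an equipotential
metal surface), the sink region at 0 V, zero-flux on every other exterior
face; the solution is then scaled linearly so the total current leaving the
active contact equals the requested injection.  Impedance falls out as
contact voltage over injected current.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import LinearOperator, cg

from .grid import VoxelGrid
from .model import LEAD_ACTIVE, TissueModel

__all__ = [
    "SinkSpec",
    "PotentialField",
    "SolverError",
    "solve_potential",
    "compute_impedance",
    "refine_local",
    "analytic_point_source",
    "contact_current",
]

_MM = 1e-3  # mm -> m


class SolverError(RuntimeError):
    pass


@dataclass
class SinkSpec:
    """Grounded (0 V) return region: a domain boundary face by default,
    or an explicit voxel mask."""

    face: str = "z-"
    mask: VoxelGrid | None = None

    def resolve(self, grid: VoxelGrid, conductive: np.ndarray) -> np.ndarray:
        if self.mask is not None:
            if not self.mask.same_lattice(grid):
                raise ValueError("sink mask is not on the model grid")
            return self.mask.values.astype(bool) & conductive
        axis = {"x": 0, "y": 1, "z": 2}[self.face[0]]
        side = self.face[1]
        sel = [slice(None)] * 3
        sel[axis] = 0 if side == "-" else -1
        out = np.zeros(grid.shape, dtype=bool)
        out[tuple(sel)] = True
        return out & conductive


@dataclass
class PotentialField:
    """Scalar potential (V) on a regular grid, scaled to ``current`` amperes.

    ``grid.values`` holds phi; voxels outside the conductive domain are
    filled with the value of the nearest conductive voxel so that
    interpolation stays finite (they carry no physical meaning and are
    excluded downstream).  ``impedance`` = contact voltage / current.
    """

    grid: VoxelGrid
    current: float
    active_label: int
    contact_voltage: float
    residual: float
    iterations: int
    conductive: VoxelGrid = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def impedance(self) -> float:
        if self.current == 0:
            raise ValueError("field has zero injected current")
        return self.contact_voltage / self.current

    def scaled(self, current: float) -> "PotentialField":
        """Same solution rescaled to a different injected current."""
        factor = current / self.current
        return PotentialField(
            grid=self.grid.like(self.grid.values * factor),
            current=current,
            active_label=self.active_label,
            contact_voltage=self.contact_voltage * factor,
            residual=self.residual,
            iterations=self.iterations,
            conductive=self.conductive,
        )


# ----------------------------------------------------------------------
# discrete operator pieces


def _face_conductances(sigma: np.ndarray, spacing: np.ndarray, axis: int) -> np.ndarray:
    """Harmonic-mean conductance (S) across faces along ``axis``.

    Shape is reduced by one along ``axis``; zero wherever either side is
    an insulator.
    """
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(None, -1)
    sl_hi[axis] = slice(1, None)
    s1 = sigma[tuple(sl_lo)]
    s2 = sigma[tuple(sl_hi)]
    harm = np.zeros_like(s1)
    ok = (s1 > 0) & (s2 > 0)
    harm[ok] = 2.0 * s1[ok] * s2[ok] / (s1[ok] + s2[ok])
    # face area over center distance, converted to meters
    h = spacing
    geom = (h[(axis + 1) % 3] * h[(axis + 2) % 3] / h[axis]) * _MM
    return harm * geom


def _pair_indices(shape: tuple[int, int, int], axis: int):
    """Flat indices (low side, high side) of all voxel faces along ``axis``."""
    flat = np.arange(int(np.prod(shape))).reshape(shape)
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(None, -1)
    sl_hi[axis] = slice(1, None)
    return flat[tuple(sl_lo)].ravel(), flat[tuple(sl_hi)].ravel()


def _connected_to_dirichlet(
    conductive: np.ndarray, active: np.ndarray, ground: np.ndarray
) -> np.ndarray:
    """Conductive voxels 6-connected to either Dirichlet region.

    Raises if the contact and ground live in disjoint components (no
    conductive path); floating pockets are dropped with a warning.
    """
    structure = ndimage.generate_binary_structure(3, 1)
    comp, _ = ndimage.label(conductive, structure=structure)
    active_comps = set(np.unique(comp[active])) - {0}
    ground_comps = set(np.unique(comp[ground])) - {0}
    if not active_comps & ground_comps:
        raise SolverError(
            "no conductive path between the active contact and the sink "
            "(singular system)"
        )
    keep = sorted(active_comps | ground_comps)
    connected = np.isin(comp, keep) & conductive
    n_dropped = int(conductive.sum() - connected.sum())
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} conductive voxels not connected to the "
            "contact or sink",
            stacklevel=3,
        )
    return connected


def _solve_dirichlet(
    grid: VoxelGrid,
    sigma: np.ndarray,
    dirichlet: np.ndarray,
    phi_dir: np.ndarray,
    tolerance: float,
    max_iter: int,
) -> tuple[np.ndarray, float, int]:
    """Solve the interior problem given Dirichlet voxels and their values.

    ``sigma`` must already be zeroed on voxels excluded from the domain.
    Returns (phi over the whole grid with Dirichlet values imposed and
    zeros elsewhere, relative residual, CG iterations).
    """
    conductive = sigma > 0
    unknown = conductive & ~dirichlet
    n = int(unknown.sum())
    if n == 0:
        raise SolverError("no unknown voxels in the conductive domain")

    index = np.full(grid.shape, -1, dtype=np.int64)
    index[unknown] = np.arange(n)
    idx_flat = index.ravel()
    unk_flat = unknown.ravel()
    dir_flat = (dirichlet & conductive).ravel()
    phi_dir_flat = phi_dir.ravel()

    diag = np.zeros(n)
    rhs = np.zeros(n)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for axis in range(3):
        g = _face_conductances(sigma, grid.spacing, axis).ravel()
        lo, hi = _pair_indices(grid.shape, axis)
        live = g > 0
        g, lo, hi = g[live], lo[live], hi[live]

        both = unk_flat[lo] & unk_flat[hi]
        il, ih = idx_flat[lo[both]], idx_flat[hi[both]]
        gb = g[both]
        rows += [il, ih]
        cols += [ih, il]
        vals += [-gb, -gb]
        np.add.at(diag, il, gb)
        np.add.at(diag, ih, gb)

        for a, b in ((lo, hi), (hi, lo)):
            mixed = unk_flat[a] & dir_flat[b]
            ia = idx_flat[a[mixed]]
            gm = g[mixed]
            np.add.at(diag, ia, gm)
            np.add.at(rhs, ia, gm * phi_dir_flat[b[mixed]])

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()

    inv_diag = 1.0 / diag
    M = LinearOperator((n, n), matvec=lambda v: inv_diag * v)
    iterations = 0

    def count(_):
        nonlocal iterations
        iterations += 1

    x, info = cg(A, rhs, rtol=tolerance, atol=0.0, maxiter=max_iter, M=M, callback=count)
    rhs_norm = np.linalg.norm(rhs)
    residual = float(np.linalg.norm(A @ x - rhs) / rhs_norm) if rhs_norm > 0 else 0.0
    if info != 0 or residual > 10 * tolerance:
        raise SolverError(
            f"linear solve did not converge (info={info}, relative residual "
            f"{residual:.3e} after {iterations} iterations)"
        )

    phi = np.where(dirichlet & conductive, phi_dir, 0.0)
    phi[unknown] = x
    return phi, residual, iterations


def _fill_nonconductive(
    phi: np.ndarray, conductive: np.ndarray, grid: VoxelGrid
) -> np.ndarray:
    """Replace values outside the conductive domain by the nearest
    conductive voxel's value (keeps interpolation finite near the lead)."""
    if conductive.all():
        return phi
    _, nearest = ndimage.distance_transform_edt(
        ~conductive, sampling=grid.spacing, return_indices=True
    )
    return phi[tuple(nearest)]


# ----------------------------------------------------------------------
# public operations


def solve_potential(
    model: TissueModel,
    active_id: int = LEAD_ACTIVE,
    current: float = 1e-3,
    sink: SinkSpec | None = None,
    tolerance: float = 1e-8,
    max_iter: int = 50_000,
) -> PotentialField:
    """Solve the monopolar excitation problem on a tissue model.

    ``active_id`` is the label marking active-contact voxels.  Boundary
    conditions: unit Dirichlet on the contact, 0 V on the sink, zero flux
    everywhere else; the result is scaled to the requested ``current``.
    """
    sink = sink or SinkSpec()
    grid = model.labels
    sigma = model.sigma_volume()
    conductive = sigma > 0

    active = model.labels.values == active_id
    if not active.any():
        raise SolverError(f"model contains no voxels with active label {active_id}")
    if not conductive[active].all():
        raise SolverError("active contact voxels must be conductive")
    sink_mask = sink.resolve(grid, conductive)
    if not sink_mask.any():
        raise SolverError("sink region is empty")
    if (sink_mask & active).any():
        raise SolverError("sink region overlaps the active contact")

    conductive = _connected_to_dirichlet(conductive, active, sink_mask)
    sigma = np.where(conductive, sigma, 0.0)

    dirichlet = active | sink_mask
    phi_dir = np.zeros(grid.shape)
    phi_dir[active] = 1.0

    phi, residual, iterations = _solve_dirichlet(
        grid, sigma, dirichlet, phi_dir, tolerance, max_iter
    )

    i_unit = contact_current(model, grid.like(phi), active_id, sigma=sigma)
    if i_unit <= 0:
        raise SolverError("non-positive contact current; check model topology")

    scale = current / i_unit
    phi = _fill_nonconductive(phi * scale, conductive, grid)

    return PotentialField(
        grid=grid.like(phi),
        current=current,
        active_label=active_id,
        contact_voltage=scale,
        residual=residual,
        iterations=iterations,
        conductive=grid.like(conductive),
    )


def contact_current(
    model: TissueModel,
    phi: VoxelGrid,
    active_id: int = LEAD_ACTIVE,
    sigma: np.ndarray | None = None,
) -> float:
    """Total current (A) leaving the voxels labeled ``active_id``, from the
    discrete face fluxes of ``phi``."""
    grid = model.labels
    if sigma is None:
        sigma = model.sigma_volume()
    active = (model.labels.values == active_id).ravel()
    cond = (sigma > 0).ravel()
    phi_flat = phi.values.ravel()
    total = 0.0
    for axis in range(3):
        g = _face_conductances(sigma, grid.spacing, axis).ravel()
        lo, hi = _pair_indices(grid.shape, axis)
        for a, b in ((lo, hi), (hi, lo)):
            m = active[a] & ~active[b] & cond[b] & (g > 0)
            total += float(np.sum(g[m] * (phi_flat[a[m]] - phi_flat[b[m]])))
    return total


def compute_impedance(fieldv: PotentialField) -> float:
    """Electrode-to-return impedance in ohms: contact voltage over current."""
    return fieldv.impedance


def refine_local(
    model: TissueModel,
    coarse: PotentialField,
    box_center: np.ndarray,
    box_size: float = 20.0,
    fine_spacing: float = 0.2,
    rerasterize=None,
    active_id: int = LEAD_ACTIVE,
    tolerance: float = 1e-8,
    max_iter: int = 50_000,
) -> tuple[PotentialField, TissueModel]:
    """Re-solve inside a cube around the contact at a finer spacing.

    Boundary values on the cube faces are trilinearly interpolated from the
    coarse solution and held fixed.  ``rerasterize(fine_grid) -> TissueModel``
    supplies geometrically re-rasterized labels; by default the coarse labels
    are nearest-neighbor resampled.  The contact voltage is adjusted by
    superposition so that the recomputed contact current on the fine grid
    equals ``coarse.current`` exactly, so ``impedance`` reflects the refined
    discretization while the solution stays consistent with the coarse far
    field on the box boundary.
    """
    box_center = np.asarray(box_center, dtype=float)
    cgrid = coarse.grid
    half = box_size / 2.0
    low = box_center - half
    high = box_center + half
    lo_idx = cgrid.world_to_index(low)
    hi_idx = cgrid.world_to_index(high)
    if np.any(lo_idx < 0) or np.any(hi_idx > np.array(cgrid.shape) - 1):
        raise ValueError("refinement box exits the coarse solution domain")
    if fine_spacing > cgrid.spacing.min() + 1e-12:
        raise ValueError("fine_spacing must not exceed the coarse spacing")

    # snap the fine lattice onto coarse voxel centers so that no-op
    # refinement (fine_spacing == coarse spacing) is exact; snap outward
    # so the fine grid always covers the requested cube
    start = (
        cgrid.origin
        + np.floor((low - cgrid.origin) / cgrid.spacing + 1e-9) * cgrid.spacing
    )
    n_vox = np.ceil((high - start) / fine_spacing - 1e-9).astype(int) + 1
    fine_grid = VoxelGrid(
        origin=start, spacing=np.full(3, fine_spacing), values=np.zeros(tuple(n_vox))
    )

    if rerasterize is not None:
        fine_model = rerasterize(fine_grid)
        if not fine_model.labels.same_lattice(fine_grid):
            raise ValueError("rerasterize returned labels on a different lattice")
        # the callback supplies geometry; conductivities follow the model
        # being solved (e.g. a trial sigma during calibration)
        fine_model = TissueModel(
            labels=fine_model.labels,
            conductivity={**fine_model.conductivity, **model.conductivity},
        )
    else:
        fine_labels = _resample_nearest(model.labels, fine_grid)
        fine_model = TissueModel(
            labels=fine_grid.like(fine_labels.astype(model.labels.values.dtype)),
            conductivity=dict(model.conductivity),
        )

    grid = fine_model.labels
    sigma = fine_model.sigma_volume()
    conductive = sigma > 0
    active = grid.values == active_id
    if not active.any():
        raise SolverError("refinement box contains no active-contact voxels")

    boundary = np.zeros(fine_grid.shape, dtype=bool)
    for axis in range(3):
        sel = [slice(None)] * 3
        sel[axis] = 0
        boundary[tuple(sel)] = True
        sel[axis] = -1
        boundary[tuple(sel)] = True
    boundary &= conductive & ~active

    conductive = _connected_to_dirichlet(conductive, active, boundary)
    sigma = np.where(conductive, sigma, 0.0)

    dirichlet = active | boundary

    # pass 1: coarse boundary values, contact at the coarse contact voltage
    phi_dir = np.zeros(fine_grid.shape)
    phi_dir[boundary] = _trilinear(cgrid, fine_grid)[boundary]
    phi_dir[active] = coarse.contact_voltage
    phi1, residual, it1 = _solve_dirichlet(
        fine_grid, sigma, dirichlet, phi_dir, tolerance, max_iter
    )
    i1 = contact_current(fine_model, fine_grid.like(phi1), active_id, sigma=sigma)

    # pass 2: unit contact voltage, grounded box boundary -> the local
    # conductance between contact and box, for the superposition correction
    unit_dir = np.zeros(fine_grid.shape)
    unit_dir[active] = 1.0
    phi_u, _, it2 = _solve_dirichlet(
        fine_grid, sigma, dirichlet, unit_dir, tolerance, max_iter
    )
    g_local = contact_current(fine_model, fine_grid.like(phi_u), active_id, sigma=sigma)
    if g_local <= 0:
        raise SolverError("refined solve produced non-positive local conductance")

    # shift the contact voltage so the fine-grid contact current matches
    dv = (coarse.current - i1) / g_local
    phi = phi1 + dv * phi_u
    contact_voltage = coarse.contact_voltage + dv
    if contact_voltage <= 0:
        raise SolverError("refined contact voltage is non-positive")
    phi = _fill_nonconductive(phi, conductive, fine_grid)

    refined = PotentialField(
        grid=fine_grid.like(phi),
        current=coarse.current,
        active_label=active_id,
        contact_voltage=contact_voltage,
        residual=residual,
        iterations=it1 + it2,
        conductive=fine_grid.like(conductive),
    )
    return refined, fine_model


# ----------------------------------------------------------------------
# resampling helpers


def _sample_indices(src: VoxelGrid, dst: VoxelGrid) -> np.ndarray:
    x, y, z = dst.axes()
    pts = np.stack(np.meshgrid(x, y, z, indexing="ij"), axis=-1)
    return ((pts - src.origin) / src.spacing).reshape(-1, 3).T


def _trilinear(src: VoxelGrid, dst: VoxelGrid) -> np.ndarray:
    """Trilinear interpolation of ``src`` values at ``dst`` voxel centers."""
    return ndimage.map_coordinates(
        src.values.astype(float), _sample_indices(src, dst), order=1, mode="nearest"
    ).reshape(dst.shape)


def _resample_nearest(src: VoxelGrid, dst: VoxelGrid) -> np.ndarray:
    return ndimage.map_coordinates(
        src.values, _sample_indices(src, dst), order=0, mode="nearest"
    ).reshape(dst.shape)


# ----------------------------------------------------------------------
# closed-form oracle


def analytic_point_source(
    current: float, sigma: float, points: np.ndarray
) -> np.ndarray:
    """Potential ``I / (4 pi sigma r)`` of a point current source at the
    origin, for points given in mm."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    points = np.asarray(points, dtype=float)
    r = np.linalg.norm(np.atleast_2d(points), axis=-1) * _MM
    if np.any(r == 0):
        raise ValueError("point coincides with the source (r = 0)")
    return current / (4.0 * np.pi * sigma * r)
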