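"""Gray-matter conductivity calibration against a measured impedance.

The simulated electrode-to-return impedance decreases monotonically with
gray-matter conductivity, so a bracketed bisection on sigma_GM (all other
tissue conductivities pinned) reproduces the clinical tuning step.  The
loop runs on the coarse grid; optionally a locally refined solve confirms
the achieved impedance and applies a multiplicative correction
(impedance x sigma is locally constant) until the refined impedance meets
the tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .field_solver import PotentialField, SinkSpec, refine_local, solve_potential
from .model import GRAY_MATTER, LEAD_ACTIVE, TissueModel

__all__ = ["CalibrationResult", "calibrate_gm_conductivity"]


class CalibrationError(RuntimeError):
    pass


@dataclass
class CalibrationResult:
    """Outcome of the conductivity calibration."""

    sigma_gm: float
    achieved_impedance: float
    target_impedance: float
    iterations: int
    bracket: tuple[float, float]
    model: TissueModel = field(repr=False, default=None)  # type: ignore[assignment]
    fieldv: PotentialField = field(repr=False, default=None)  # type: ignore[assignment]
    evaluations: list[tuple[float, float]] = field(default_factory=list, repr=False)

    @property
    def relative_error(self) -> float:
        return abs(self.achieved_impedance - self.target_impedance) / self.target_impedance


def calibrate_gm_conductivity(
    model: TissueModel,
    target_impedance: float,
    current: float = 1e-3,
    active_id: int = LEAD_ACTIVE,
    sink: SinkSpec | None = None,
    bracket: tuple[float, float] = (0.02, 0.5),
    tol: float = 0.005,
    gm_label: int = GRAY_MATTER,
    max_iter: int = 60,
    refine_opts: dict | None = None,
    solver_tolerance: float = 1e-8,
) -> CalibrationResult:
    """Bisect sigma of ``gm_label`` until the simulated impedance matches
    ``target_impedance`` within relative ``tol``.

    ``refine_opts`` (optional) configures a confirmation solve on a locally
    refined grid: keys ``box_center``, ``box_size``, ``fine_spacing`` and
    optionally ``rerasterize`` / ``max_steps``.  When given, the achieved
    impedance is the refined one and sigma is corrected multiplicatively
    until it meets the tolerance.

    Deterministic; raises if the bracket does not enclose the target or if
    the impedance is not decreasing across the bracket.
    """
    lo, hi = bracket
    if not (0 < lo < hi):
        raise ValueError(f"bracket must be positive and increasing, got {bracket}")
    if target_impedance <= 0:
        raise ValueError("target impedance must be positive")

    evaluations: list[tuple[float, float]] = []

    def simulate(sigma: float) -> tuple[float, TissueModel, PotentialField]:
        m = model.with_conductivity(gm_label, sigma)
        f = solve_potential(
            m, active_id=active_id, current=current, sink=sink,
            tolerance=solver_tolerance,
        )
        evaluations.append((sigma, f.impedance))
        return f.impedance, m, f

    def refined_impedance(m: TissueModel, f: PotentialField) -> tuple[float, PotentialField]:
        r, _ = refine_local(
            m,
            f,
            box_center=refine_opts["box_center"],
            box_size=refine_opts.get("box_size", 20.0),
            fine_spacing=refine_opts["fine_spacing"],
            rerasterize=refine_opts.get("rerasterize"),
            active_id=active_id,
            tolerance=solver_tolerance,
        )
        return r.impedance, r

    r_lo, _, _ = simulate(lo)
    r_hi, _, _ = simulate(hi)
    if r_lo <= r_hi:
        raise CalibrationError(
            f"impedance is not decreasing across the bracket: "
            f"R({lo}) = {r_lo:.1f} ohm <= R({hi}) = {r_hi:.1f} ohm"
        )
    if not (r_hi < target_impedance < r_lo):
        raise CalibrationError(
            f"target {target_impedance:.1f} ohm outside bracket impedance range "
            f"[R({hi}) = {r_hi:.1f}, R({lo}) = {r_lo:.1f}] ohm"
        )

    iterations = 0
    sigma = lo
    achieved, best_model, best_field = r_lo, None, None
    while iterations < max_iter:
        iterations += 1
        sigma = 0.5 * (lo + hi)
        achieved, best_model, best_field = simulate(sigma)
        if abs(achieved - target_impedance) / target_impedance <= tol:
            break
        if achieved > target_impedance:
            lo = sigma  # need more conductivity
        else:
            hi = sigma
    else:
        raise CalibrationError(
            f"bisection did not reach tolerance {tol} in {max_iter} iterations "
            f"(last impedance {achieved:.1f} ohm vs target {target_impedance:.1f})"
        )

    best_f: PotentialField = best_field  # type: ignore[assignment]
    if refine_opts is not None:
        # confirm on the refined grid; correct sigma using R*sigma ~ const
        max_steps = refine_opts.get("max_steps", 5)
        achieved, best_f = refined_impedance(best_model, best_field)
        step = 0
        while (
            abs(achieved - target_impedance) / target_impedance > tol
            and step < max_steps
        ):
            step += 1
            iterations += 1
            sigma = float(np.clip(sigma * achieved / target_impedance, *bracket))
            _, best_model, coarse_f = simulate(sigma)
            achieved, best_f = refined_impedance(best_model, coarse_f)
        if abs(achieved - target_impedance) / target_impedance > tol:
            raise CalibrationError(
                f"refined correction did not reach tolerance {tol}: "
                f"achieved {achieved:.1f} ohm vs target {target_impedance:.1f}"
            )

    return CalibrationResult(
        sigma_gm=float(sigma),
        achieved_impedance=float(achieved),
        target_impedance=float(target_impedance),
        iterations=iterations,
        bracket=bracket,
        model=best_model,
        fieldv=best_f,
        evaluations=evaluations,
    )
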