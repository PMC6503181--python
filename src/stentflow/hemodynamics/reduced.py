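"""Reduced-order (network) flow backend.

Fast analytic surrogate for the 3D solver: each inter-station interval
contributes a local Poiseuille resistance ``8 mu ds / (pi rbar^4)``, and each
post-stenotic expansion a Borda-Carnot separation loss
``dP = 1/2 rho Q^2 (1/A_min - 1/A_rec)^2``.  The flow rate solves the scalar
balance

    P_inlet - P_venous = R_v Q + K Q^2 + R_distal Q

by bracketed root-finding on the (strictly monotone) left-hand side.  The
axial pressure profile follows by accumulating the losses from the inlet,
with each expansion loss distributed linearly over its diverging segment.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import brentq

from ..geometry import VesselGeometry, validate_vessel
from .core import BloodProperties, BoundaryConditions, FlowSolution, SolverError

__all__ = ["solve_reduced", "poiseuille_resistance", "borda_carnot_losses"]

#: laminar-regime guard: warn above this Reynolds number
REYNOLDS_WARN = 2000.0


def poiseuille_resistance(vessel: VesselGeometry, viscosity: float) -> np.ndarray:
    """Per-interval Poiseuille resistances (Pa.s/m^3), SI units.

    Interval i spans stations i..i+1 with mean radius ``(r_i + r_{i+1})/2``.
    """
    s_m = vessel.s * 1e-3
    r_m = vessel.radii * 1e-3
    ds = np.diff(s_m)
    r_bar = 0.5 * (r_m[:-1] + r_m[1:])
    return 8.0 * viscosity * ds / (np.pi * r_bar**4)


def borda_carnot_losses(
    vessel: VesselGeometry, density: float
) -> list[tuple[int, int, float]]:
    """Expansion (separation) losses downstream of each stenosis throat.

    Returns ``(i_throat, i_recovery, K)`` triples where the loss is
    ``K * Q^2`` with ``K = 1/2 rho (1/A_min - 1/A_rec)^2`` (SI), attributed
    to the diverging segment between the throat and the recovery station.
    """
    r = vessel.radii * 1e-3
    area = np.pi * r**2
    n = len(r)
    dr = np.diff(r)
    losses = []
    i = 1
    while i < n - 1:
        if dr[i - 1] < 0 and dr[i] >= 0:  # local minimum: a throat
            j = i
            while j < n - 1 and r[j + 1] >= r[j]:
                j += 1
            a_min, a_rec = area[i], area[j]
            if a_rec > a_min:
                k = 0.5 * density * (1.0 / a_min - 1.0 / a_rec) ** 2
                losses.append((i, j, k))
            i = j
        else:
            i += 1
    return losses


def solve_reduced(
    vessel: VesselGeometry,
    bc: BoundaryConditions,
    blood: BloodProperties = BloodProperties(),
) -> FlowSolution:
    """Solve the lumped network model for flow and axial pressure.

    Root-finding tolerance is 1e-10 relative on Q; the outlet identity
    ``P_out = P_venous + Q * R_distal`` then holds to the same accuracy.
    """
    validate_vessel(vessel)
    r_seg = poiseuille_resistance(vessel, blood.viscosity)
    r_v = float(r_seg.sum())
    losses = borda_carnot_losses(vessel, blood.density)
    k_total = sum(k for _, _, k in losses)

    dp_total = bc.p_inlet - bc.p_venous

    def residual(q: float) -> float:
        return r_v * q + k_total * q * q + bc.r_distal * q - dp_total

    if dp_total <= 0.0:
        q = 0.0
    else:
        q_hi = dp_total / bc.r_distal  # residual(q_hi) >= 0 since R_v, K >= 0
        if residual(q_hi) < 0:  # numerically impossible; guarded anyway
            raise SolverError("reduced-model root bracketing failed")
        q = brentq(residual, 0.0, q_hi, rtol=1e-12, maxiter=200)

    # cumulative pressure profile
    cum_visc = np.concatenate([[0.0], np.cumsum(r_seg)])  # at stations
    p = bc.p_inlet - q * cum_visc
    for i_th, i_rec, k in losses:
        dp_loss = k * q * q
        frac = np.zeros_like(p)
        frac[i_rec:] = 1.0
        seg = slice(i_th, i_rec + 1)
        span = vessel.s[i_rec] - vessel.s[i_th]
        if span > 0:
            frac[seg] = (vessel.s[seg] - vessel.s[i_th]) / span
        p -= dp_loss * frac

    r_min = float(vessel.radii.min()) * 1e-3
    reynolds = (
        blood.density * (2.0 * q / (np.pi * r_min**2)) * r_min / blood.viscosity
        if q > 0
        else 0.0
    )
    if reynolds > REYNOLDS_WARN:
        warnings.warn(
            f"Reynolds number {reynolds:.0f} exceeds the laminar guard "
            f"({REYNOLDS_WARN:.0f}); the steady laminar model may be inaccurate",
            stacklevel=2,
        )

    outlet_err = (
        abs(p[-1] - bc.p_venous - q * bc.r_distal) / bc.p_inlet if q > 0 else 0.0
    )
    return FlowSolution(
        backend="reduced",
        q=q,
        s=vessel.s.copy(),
        pressure=p,
        bc=bc,
        blood=blood,
        reynolds=reynolds,
        report={
            "converged": True,
            "vessel_resistance": r_v,
            "expansion_coefficient": k_total,
            "n_expansions": len(losses),
            "outlet_relation_error": outlet_err,
        },
    )
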