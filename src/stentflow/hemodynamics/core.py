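"""Shared hemodynamic types: fluid properties, boundary conditions, solutions.

FFR convention: the fractional flow reserve between two marked points is the
ratio of distal to proximal pressure, both referenced to a venous pressure of
zero, under steady (hyperemic) flow.  Values at or below 0.80 indicate a
flow-limiting stenosis.

Units: geometry enters in mm; everything in this layer is SI (Pa, m, m^3/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MMHG_TO_PA",
    "DEFAULT_DISTAL_RESISTANCE",
    "BloodProperties",
    "BoundaryConditions",
    "FlowSolution",
    "FFRResult",
    "SolverError",
    "compute_vffr",
]

#: conversion factor, 1 mmHg in Pa
MMHG_TO_PA = 133.322

#: generic distal (myocardial) resistance, Pa.s/m^3 — population-average value
#: used when no invasive wire measurement is available
DEFAULT_DISTAL_RESISTANCE = 8.721e9

#: default mean proximal (aortic) pressure, mmHg
DEFAULT_PA_MMHG = 93.0


class SolverError(RuntimeError):
    """A flow solve failed to converge; carries the residual history."""

    def __init__(self, message: str, history: list | None = None):
        super().__init__(message)
        self.history = history or []


@dataclass(frozen=True)
class BloodProperties:
    """Newtonian blood: density (kg/m^3) and dynamic viscosity (Pa.s)."""

    density: float = 1056.0
    viscosity: float = 3.5e-3

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass(frozen=True)
class BoundaryConditions:
    """Pressure inlet + lumped distal resistance outlet.

    ``p_inlet`` is the mean proximal (aortic) pressure in Pa; ``r_distal``
    the lumped microvascular resistance in Pa.s/m^3; ``p_venous`` the
    reference pressure on the far side of that resistance (0 by the usual
    FFR convention).
    """

    p_inlet: float
    r_distal: float = DEFAULT_DISTAL_RESISTANCE
    p_venous: float = 0.0

    def __post_init__(self) -> None:
        if self.p_venous < 0:
            raise ValueError("p_venous must be >= 0")
        if self.p_inlet < self.p_venous:
            raise ValueError("p_inlet must not be below p_venous")
        if self.r_distal <= 0:
            raise ValueError("r_distal must be positive")

    @classmethod
    def from_mmhg(
        cls,
        pa_mmhg: float = DEFAULT_PA_MMHG,
        r_distal: float = DEFAULT_DISTAL_RESISTANCE,
        p_venous: float = 0.0,
    ) -> "BoundaryConditions":
        return cls(p_inlet=pa_mmhg * MMHG_TO_PA, r_distal=r_distal, p_venous=p_venous)


@dataclass
class FlowSolution:
    """Result of a flow solve on one vessel.

    ``s`` (mm) and ``pressure`` (Pa) give the section-averaged axial pressure
    profile; ``pressure_at`` interpolates it.  The 3D backend additionally
    exposes cell fields.  ``report`` carries the convergence record
    (iterations, final residuals, outlet-coupling error).
    """

    backend: str
    q: float  # volumetric flow, m^3/s
    s: np.ndarray  # mm
    pressure: np.ndarray  # Pa
    bc: BoundaryConditions
    blood: BloodProperties
    report: dict = field(default_factory=dict)
    reynolds: float = 0.0
    cell_pressure: np.ndarray | None = None
    cell_velocity: np.ndarray | None = None
    cell_centers: np.ndarray | None = None

    def pressure_at(self, s_mm: float | np.ndarray) -> np.ndarray:
        """Section-averaged absolute pressure (Pa) at arc length ``s_mm``."""
        s_arr = np.asarray(s_mm, dtype=float)
        if np.any(s_arr < self.s[0] - 1e-9) or np.any(s_arr > self.s[-1] + 1e-9):
            raise ValueError(
                f"arc length outside the solved domain [{self.s[0]:.3f}, "
                f"{self.s[-1]:.3f}] mm"
            )
        return np.interp(s_arr, self.s, self.pressure)

    @property
    def p_outlet(self) -> float:
        return float(self.pressure[-1])


@dataclass(frozen=True)
class FFRResult:
    """Pd/Pa pressure ratio between two marked arc lengths."""

    s_proximal: float
    s_distal: float
    p_proximal: float
    p_distal: float

    @property
    def vffr(self) -> float:
        if self.p_distal == self.p_proximal:  # zero-flow limit: exactly 1
            return 1.0
        return self.p_distal / self.p_proximal


def compute_vffr(solution: FlowSolution, s_proximal: float, s_distal: float) -> FFRResult:
    """Virtual FFR between two marked points: ``P(s_distal) / P(s_proximal)``.

    Pressures are section-averaged absolute values (venous reference 0).  A
    zero-flow solution has a uniform pressure field and yields exactly 1.
    """
    if s_proximal >= s_distal:
        raise ValueError("s_proximal must be < s_distal")
    p_prox = float(solution.pressure_at(s_proximal))
    p_dist = float(solution.pressure_at(s_distal))
    return FFRResult(s_proximal, s_distal, p_prox, p_dist)
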