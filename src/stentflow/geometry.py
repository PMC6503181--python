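"""Canonical vessel representation: ordered circular cross-sections on a centerline.

A diseased coronary artery is modeled as a set of connected circular
cross-sections following the points at the center of the vessel path.  Each
section carries an arc length ``s`` (mm, 0 at the proximal inlet, increasing
distally), a 3D center point, a unit tangent and a lumen radius.  This module
owns the container type, its validator, plain-text file I/O, arc-length
resampling, and a synthetic stenosed-vessel generator used as the repository's
fixture factory (it stands in for an angiographic 3D reconstruction, which is
out of scope here).

Units: millimetres throughout this layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CrossSection",
    "VesselGeometry",
    "StenosisSpec",
    "VesselFormatError",
    "make_synthetic_vessel",
    "read_vessel",
    "write_vessel",
    "resample_vessel",
    "validate_vessel",
]

#: canonical arc-length sampling step (mm); fine enough that a 20 mm stent
#: spans at least 80 stations.
CANONICAL_STEP = 0.25


class VesselFormatError(ValueError):
    """Raised when a canonical vessel file violates the format contract."""


@dataclass(frozen=True)
class CrossSection:
    """One circular lumen cross-section.

    Attributes
    ----------
    center : (3,) float array, mm
    tangent : (3,) float array, unit norm
    radius : float, mm, > 0
    s : float, mm, arc length from the inlet
    """

    center: np.ndarray
    tangent: np.ndarray
    radius: float
    s: float


@dataclass
class VesselGeometry:
    """Ordered circular cross-sections along a 3D centerline.

    The single source of truth for anatomy.  Stored internally as arrays for
    efficiency; ``sections`` materializes :class:`CrossSection` objects.

    Attributes
    ----------
    centers : (n, 3) float array, mm
    radii : (n,) float array, mm
    s : (n,) float array, mm; strictly increasing, ``s[0] == 0``
    name : str
    units : str, tag only ("mm")
    """

    centers: np.ndarray
    radii: np.ndarray
    s: np.ndarray
    name: str = "vessel"
    units: str = "mm"

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.s = np.asarray(self.s, dtype=float)

    # -- derived quantities -------------------------------------------------

    @property
    def n_sections(self) -> int:
        return len(self.s)

    @property
    def length(self) -> float:
        """Total arc length (mm)."""
        return float(self.s[-1] - self.s[0])

    def tangents(self) -> np.ndarray:
        """Unit tangents by central differences (one-sided at the ends)."""
        t = np.gradient(self.centers, self.s, axis=0)
        norms = np.linalg.norm(t, axis=1, keepdims=True)
        return t / norms

    @property
    def sections(self) -> list[CrossSection]:
        tang = self.tangents()
        return [
            CrossSection(self.centers[i], tang[i], float(self.radii[i]), float(self.s[i]))
            for i in range(self.n_sections)
        ]

    def radius_at(self, s: float | np.ndarray) -> np.ndarray:
        """Lumen radius linearly interpolated at arc length ``s`` (mm)."""
        return np.interp(s, self.s, self.radii)

    def copy(self) -> "VesselGeometry":
        return VesselGeometry(
            self.centers.copy(), self.radii.copy(), self.s.copy(), self.name, self.units
        )


def validate_vessel(vessel: VesselGeometry, *, chord_tol: float = 0.01) -> None:
    """Check the VesselGeometry invariants; raise ``ValueError`` on violation.

    Invariants: at least 2 sections; radii positive; s strictly increasing
    from 0; consecutive centers distinct; cumulative chord length consistent
    with ``s`` within ``chord_tol`` (relative).
    """
    if vessel.n_sections < 2:
        raise ValueError("vessel must have at least 2 cross-sections")
    if not np.all(vessel.radii > 0):
        i = int(np.argmin(vessel.radii))
        raise ValueError(f"non-positive radius {vessel.radii[i]} at section {i}")
    if abs(vessel.s[0]) > 1e-12:
        raise ValueError(f"arc length must start at 0, got {vessel.s[0]}")
    ds = np.diff(vessel.s)
    if not np.all(ds > 0):
        raise ValueError("arc length not increasing")
    chords = np.linalg.norm(np.diff(vessel.centers, axis=0), axis=1)
    if np.any(chords == 0):
        raise ValueError("consecutive centers must be distinct")
    total_chord = chords.sum()
    if abs(total_chord - vessel.length) > chord_tol * vessel.length:
        raise ValueError(
            f"arc length {vessel.length:.4f} inconsistent with cumulative "
            f"chord length {total_chord:.4f} (> {chord_tol:.0%})"
        )


# ---------------------------------------------------------------------------
# Synthetic vessel generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StenosisSpec:
    """A focal narrowing for the synthetic generator.

    severity is the fractional *diameter* reduction in [0, 1); the profile is
    a smooth cosine bump, 1 at ``s_center`` and 0 outside
    ``[s_center - length/2, s_center + length/2]``.
    """

    s_center: float
    length: float
    severity: float
    profile: str = "cosine"

    @property
    def interval(self) -> tuple[float, float]:
        return (self.s_center - self.length / 2.0, self.s_center + self.length / 2.0)

    def bump(self, s: np.ndarray) -> np.ndarray:
        """Unimodal C1 profile: ``(1 + cos(2π(s − s_center)/length))/2`` clipped."""
        x = np.asarray(s, dtype=float) - self.s_center
        inside = np.abs(x) <= self.length / 2.0
        out = np.zeros_like(x, dtype=float)
        out[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * x[inside] / self.length))
        return out


def _check_stenoses(stenoses: list[StenosisSpec], length: float) -> None:
    for st in stenoses:
        if not 0.0 <= st.severity < 1.0:
            raise ValueError(
                f"severity must be in [0, 1), got {st.severity} "
                "(total occlusions are excluded)"
            )
        if st.length <= 0:
            raise ValueError(f"stenosis length must be positive, got {st.length}")
        lo, hi = st.interval
        if lo < 0 or hi > length:
            raise ValueError(
                f"stenosis at s={st.s_center} (span [{lo:.2f}, {hi:.2f}] mm) "
                f"extends outside the vessel [0, {length}]"
            )
    ordered = sorted(stenoses, key=lambda st: st.s_center)
    for a, b in zip(ordered, ordered[1:]):
        if a.interval[1] > b.interval[0]:
            raise ValueError(
                f"overlapping stenoses at s={a.s_center} and s={b.s_center}"
            )


def make_synthetic_vessel(
    length: float,
    base_radius: float,
    stenoses: list[StenosisSpec] | None = None,
    curvature: float = 0.0,
    step: float = CANONICAL_STEP,
    seed: int = 0,
    radius_noise: float = 0.0,
    name: str = "synthetic",
) -> VesselGeometry:
    """Generate a straight or uniformly curved tube with parameterized stenoses.

    Parameters
    ----------
    length : mm, total arc length.
    base_radius : mm, healthy lumen radius.
    stenoses : non-overlapping :class:`StenosisSpec`; the radius profile is
        ``base_radius * (1 - Σ severity_i * bump_i(s))``.
    curvature : 1/mm; 0 gives a straight axis, otherwise a circular arc of
        radius ``1/curvature`` in the x–z plane.
    step : mm, sampling step; the last interval may be short.
    seed : seeds the radius-noise stream; identical arguments and seed give
        identical output.
    radius_noise : relative Gaussian perturbation of the radii (default 0,
        i.e. a noiseless profile).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if base_radius <= 0:
        raise ValueError("base_radius must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    stenoses = list(stenoses or [])
    _check_stenoses(stenoses, length)

    s = np.arange(0.0, length, step)
    if length - s[-1] > 1e-9 * max(length, 1.0):
        s = np.append(s, length)

    reduction = np.zeros_like(s)
    for st in stenoses:
        reduction += st.severity * st.bump(s)
    radii = base_radius * (1.0 - reduction)

    if radius_noise > 0.0:
        rng = np.random.default_rng(seed)
        radii = radii * (1.0 + radius_noise * rng.standard_normal(len(s)))
        radii = np.clip(radii, 1e-3 * base_radius, None)

    if curvature == 0.0:
        centers = np.column_stack([np.zeros_like(s), np.zeros_like(s), s])
    else:
        rc = 1.0 / curvature
        # circular arc in the x-z plane, arc-length parameterized
        centers = np.column_stack(
            [rc * (1.0 - np.cos(s / rc)), np.zeros_like(s), rc * np.sin(s / rc)]
        )
        # s must stay consistent with chord length: rebuild from chords
        chords = np.linalg.norm(np.diff(centers, axis=0), axis=1)
        s_chord = np.concatenate([[0.0], np.cumsum(chords)])
        radii = np.interp(s_chord, s, radii)
        s = s_chord

    vessel = VesselGeometry(centers, radii, s, name=name)
    validate_vessel(vessel)
    return vessel


# ---------------------------------------------------------------------------
# Canonical file format: '#' comments, then "s_mm x_mm y_mm z_mm radius_mm"
# ---------------------------------------------------------------------------


def write_vessel(vessel: VesselGeometry, path) -> None:
    """Write a vessel to the canonical plain-text format (12 significant digits)."""
    with open(path, "w") as fh:
        fh.write(f"# stentflow vessel: {vessel.name}\n")
        fh.write("# columns: s_mm x_mm y_mm z_mm radius_mm\n")
        for i in range(vessel.n_sections):
            x, y, z = vessel.centers[i]
            fh.write(
                f"{vessel.s[i]:.12g} {x:.12g} {y:.12g} {z:.12g} {vessel.radii[i]:.12g}\n"
            )


def read_vessel(path) -> VesselGeometry:
    """Read a canonical vessel file; malformed lines are reported by number."""
    s_list: list[float] = []
    centers: list[list[float]] = []
    radii: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 5:
                raise VesselFormatError(
                    f"{path}: line {lineno}: expected 5 columns, got {len(parts)}"
                )
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise VesselFormatError(f"{path}: line {lineno}: {exc}") from None
            if vals[4] <= 0:
                raise VesselFormatError(
                    f"{path}: line {lineno}: non-positive radius {vals[4]}"
                )
            if s_list and vals[0] <= s_list[-1]:
                raise VesselFormatError(
                    f"{path}: line {lineno}: arc length not increasing"
                )
            s_list.append(vals[0])
            centers.append(vals[1:4])
            radii.append(vals[4])
    if len(s_list) < 2:
        raise VesselFormatError(f"{path}: fewer than 2 cross-sections")
    vessel = VesselGeometry(np.array(centers), np.array(radii), np.array(s_list))
    validate_vessel(vessel)
    return vessel


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def resample_vessel(vessel: VesselGeometry, step: float = CANONICAL_STEP) -> VesselGeometry:
    """Resample uniformly in arc length (the last interval may be short).

    Centers and radii are interpolated linearly along the existing polyline,
    so interpolated values never overshoot their neighbors and total length
    is preserved to within one step.  Idempotent for an already-uniform grid.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if step > vessel.length:
        raise ValueError(
            f"step {step} mm exceeds vessel length {vessel.length:.3f} mm"
        )
    s0, s1 = float(vessel.s[0]), float(vessel.s[-1])
    s_new = np.arange(s0, s1, step)
    if s1 - s_new[-1] > 1e-9 * max(s1, 1.0):
        s_new = np.append(s_new, s1)
    centers = np.column_stack(
        [np.interp(s_new, vessel.s, vessel.centers[:, k]) for k in range(3)]
    )
    radii = np.interp(s_new, vessel.s, vessel.radii)
    out = VesselGeometry(centers, radii, s_new - s0, vessel.name, vessel.units)
    validate_vessel(out)
    return out
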