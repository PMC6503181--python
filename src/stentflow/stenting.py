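"""Virtual stent deployment.

An idealized stent is replicated in the cross-section model by (1) smoothing
the centerline trajectory over the stented segment with a least-squares cubic
spline and (2) correcting cross-sectional radii: inside the stent the lumen is
scaffolded out to the stent radius (``max(r, D/2)``), with a short linear
taper at each edge so the mesher and solver never see a step discontinuity.

Deployment is idealized — perfect circular expansion with full apposition —
so a virtual stent never narrows the lumen and sections already wider than
the stent are left alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_lsq_spline

from .geometry import VesselGeometry, validate_vessel

__all__ = ["StentSpec", "deploy_stent", "deploy_stents", "TAPER_LENGTH"]

#: taper length (mm) at each stent edge over which the scaffolded radius
#: blends linearly back to the native lumen.
TAPER_LENGTH = 1.0

#: spacing (mm) of interior spline knots for trajectory smoothing; wide
#: enough that in-segment wiggle is straightened while overall vessel
#: curvature is followed.
_KNOT_SPACING = 5.0


@dataclass(frozen=True)
class StentSpec:
    """An idealized stent marked by proximal/distal arc lengths and a diameter.

    ``s_proximal``/``s_distal`` are the red/blue marker positions (mm);
    ``diameter`` is the nominal expanded stent diameter (mm).
    """

    s_proximal: float
    s_distal: float
    diameter: float

    def __post_init__(self) -> None:
        if self.s_proximal >= self.s_distal:
            raise ValueError(
                f"s_proximal ({self.s_proximal}) must be < s_distal ({self.s_distal})"
            )
        if self.diameter <= 0:
            raise ValueError(f"stent diameter must be positive, got {self.diameter}")

    @property
    def length(self) -> float:
        return self.s_distal - self.s_proximal

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


def _scaffold_weight(s: np.ndarray, stent: StentSpec, taper: float) -> np.ndarray:
    """1 inside the stent, linear ramp to 0 over ``taper`` mm outside."""
    w = np.zeros_like(s, dtype=float)
    inside = (s >= stent.s_proximal) & (s <= stent.s_distal)
    w[inside] = 1.0
    if taper > 0:
        prox = (s < stent.s_proximal) & (s > stent.s_proximal - taper)
        w[prox] = 1.0 - (stent.s_proximal - s[prox]) / taper
        dist = (s > stent.s_distal) & (s < stent.s_distal + taper)
        w[dist] = 1.0 - (s[dist] - stent.s_distal) / taper
    return w


def _smooth_segment(vessel: VesselGeometry, stent: StentSpec) -> np.ndarray:
    """Least-squares cubic-spline fit of the stented trajectory.

    The fit window is the stent interval plus one margin station beyond each
    end; a linear correction pins the fit to the original margin points so the
    smoothed trajectory joins the unstented path continuously.  Returns the
    full (n, 3) center array with the segment replaced.
    """
    s = vessel.s
    idx = np.where((s >= stent.s_proximal) & (s <= stent.s_distal))[0]
    if len(idx) < 4:
        return vessel.centers.copy()  # too few stations to re-fit
    lo = max(idx[0] - 1, 0)
    hi = min(idx[-1] + 1, len(s) - 1)
    seg = np.arange(lo, hi + 1)
    ss = s[seg]

    n_int = int((ss[-1] - ss[0]) // _KNOT_SPACING)
    interior = np.linspace(ss[0], ss[-1], n_int + 2)[1:-1] if n_int > 0 else np.array([])
    t = np.concatenate([[ss[0]] * 4, interior, [ss[-1]] * 4])

    centers = vessel.centers.copy()
    fitted = np.empty((len(seg), 3))
    for k in range(3):
        spl = make_lsq_spline(ss, vessel.centers[seg, k], t, k=3)
        fitted[:, k] = spl(ss)
    # pin the margin endpoints exactly (linear-in-s correction, which lies in
    # the cubic spline space, so re-deployment reproduces the same fit)
    d0 = vessel.centers[seg[0]] - fitted[0]
    d1 = vessel.centers[seg[-1]] - fitted[-1]
    frac = ((ss - ss[0]) / (ss[-1] - ss[0]))[:, None]
    fitted += (1.0 - frac) * d0 + frac * d1
    centers[seg] = fitted
    return centers


def deploy_stent(
    vessel: VesselGeometry, stent: StentSpec, taper: float = TAPER_LENGTH
) -> VesselGeometry:
    """Deploy one idealized virtual stent; returns a new vessel.

    The stented trajectory is smoothed with a cubic spline and radii are
    corrected to ``max(r, D/2)`` inside the stent, with a ``taper``-mm linear
    blend at each edge.  Stations farther than the taper from the stent are
    untouched.  Arc lengths are rebuilt from the smoothed chords.
    """
    if stent.s_proximal < vessel.s[0] - 1e-9 or stent.s_distal > vessel.s[-1] + 1e-9:
        raise ValueError(
            f"stent [{stent.s_proximal}, {stent.s_distal}] mm extends beyond "
            f"the vessel [0, {vessel.length:.3f}] mm"
        )

    w = _scaffold_weight(vessel.s, stent, taper)
    radii = np.maximum(vessel.radii, stent.radius * w)
    centers = _smooth_segment(vessel, stent)

    chords = np.linalg.norm(np.diff(centers, axis=0), axis=1)
    s_new = np.concatenate([[0.0], np.cumsum(chords)])
    out = VesselGeometry(centers, radii, s_new, vessel.name, vessel.units)
    validate_vessel(out)
    return out


def deploy_stents(
    vessel: VesselGeometry, stents: list[StentSpec], taper: float = TAPER_LENGTH
) -> VesselGeometry:
    """Deploy several stents sequentially, proximal to distal.

    Overlapping stents behave as the union interval with the larger diameter
    in the overlap (a consequence of the ``max`` radius rule).
    """
    if not stents:
        raise ValueError("stent list must be non-empty")
    out = vessel
    for stent in sorted(stents, key=lambda st: st.s_proximal):
        out = deploy_stent(out, stent, taper)
    return out
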