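"""Study-level analyses: tandem-lesion strategies and agreement statistics.

For serial (tandem) stenoses a pressure wire cannot attribute the aggregate
FFR to the individual lesions, because each stenosis caps the hyperemic flow
seen by the others.  Virtually removing each stenosis in turn — deploying an
idealized stent over one lesion, re-solving, and reading the distal vFFR —
reveals each lesion's true contribution; :func:`tandem_analysis` enumerates
every non-empty stenting strategy.

The agreement statistics mirror standard method-comparison practice for
paired FFR measurements: Bland-Altman bias and limits of agreement (2 SD),
Pearson correlation with a through-origin fitted line, and threshold-based
diagnostic accuracy (positive class: FFR <= 0.80, i.e. ischemia).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geometry import VesselGeometry, resample_vessel
from .hemodynamics import (
    BloodProperties,
    BoundaryConditions,
    compute_vffr,
    solve_3d,
    solve_reduced,
)
from .stenting import StentSpec, deploy_stents

__all__ = [
    "LesionSpec",
    "StrategyResult",
    "StrategyReport",
    "PairedFFR",
    "tandem_analysis",
    "bland_altman",
    "diagnostic_accuracy",
    "correlation",
]

#: cap on exhaustive strategy enumeration (2^6 - 1 = 63 solves)
MAX_LESIONS = 6


@dataclass(frozen=True)
class LesionSpec:
    """A stent-able lesion: the arc-length interval to scaffold and the
    reference (healthy) vessel diameter in mm used to size the stent."""

    s_start: float
    s_end: float
    reference_diameter: float

    def to_stent(self) -> StentSpec:
        return StentSpec(self.s_start, self.s_end, self.reference_diameter)


@dataclass(frozen=True)
class StrategyResult:
    lesions: tuple[int, ...]  # indices of the lesions stented
    stents: tuple[StentSpec, ...]
    vffr: float
    delta_vs_baseline: float


@dataclass
class StrategyReport:
    """All stenting strategies for one vessel, ordered by subset size then
    lesion position; ``best`` is the strategy with the highest distal vFFR."""

    baseline_vffr: float
    strategies: list[StrategyResult] = field(default_factory=list)
    s_measure: tuple[float, float] = (0.0, 0.0)
    backend: str = "reduced"

    @property
    def best(self) -> StrategyResult:
        return max(self.strategies, key=lambda st: st.vffr)

    def vffr_of(self, lesions: tuple[int, ...]) -> float:
        for st in self.strategies:
            if st.lesions == tuple(sorted(lesions)):
                return st.vffr
        raise KeyError(f"no strategy {lesions}")


def tandem_analysis(
    vessel: VesselGeometry,
    lesions: list[LesionSpec],
    bc: BoundaryConditions,
    blood: BloodProperties = BloodProperties(),
    backend: str = "reduced",
    s_measure: tuple[float, float] | None = None,
    max_lesions: int = MAX_LESIONS,
    mesh_kwargs: dict | None = None,
) -> StrategyReport:
    """Solve the baseline and every non-empty lesion subset virtually stented.

    ``s_measure`` marks the proximal/distal points between which the vFFR is
    read (defaults to the whole vessel).  Enumeration is capped at
    ``max_lesions`` (override explicitly for more than 6).
    """
    if not lesions:
        raise ValueError("at least one lesion is required")
    if len(lesions) > max_lesions:
        raise ValueError(
            f"{len(lesions)} lesions would need {2 ** len(lesions) - 1} solves; "
            f"raise max_lesions to override the cap of {max_lesions}"
        )
    ordered = sorted(enumerate(lesions), key=lambda kv: kv[1].s_start)
    for (_, a), (_, b) in zip(ordered, ordered[1:]):
        if a.s_end > b.s_start:
            raise ValueError(
                f"overlapping lesion intervals [{a.s_start}, {a.s_end}] and "
                f"[{b.s_start}, {b.s_end}]"
            )

    if s_measure is None:
        s_measure = (0.0, vessel.length)

    def solve_for(v: VesselGeometry) -> float:
        if backend == "reduced":
            sol = solve_reduced(v, bc, blood)
        elif backend == "fvm3d":
            from .meshing import build_volume_mesh

            mesh = build_volume_mesh(v, **(mesh_kwargs or {}))
            sol = solve_3d(mesh, bc, blood)
        else:
            raise ValueError(f"unknown backend {backend!r}")
        lo = max(s_measure[0], sol.s[0])
        hi = min(s_measure[1], sol.s[-1])
        return compute_vffr(sol, lo, hi).vffr

    baseline = solve_for(vessel)
    report = StrategyReport(
        baseline_vffr=baseline, s_measure=s_measure, backend=backend
    )
    n = len(lesions)
    for size in range(1, n + 1):
        for combo in itertools.combinations(range(n), size):
            stents = tuple(lesions[i].to_stent() for i in combo)
            stented = deploy_stents(vessel, list(stents))
            vffr = solve_for(stented)
            report.strategies.append(
                StrategyResult(combo, stents, vffr, vffr - baseline)
            )
    return report


# ---------------------------------------------------------------------------
# Paired-measurement statistics
# ---------------------------------------------------------------------------


@dataclass
class PairedFFR:
    """Paired (measured, virtual) FFR values, each in (0, 1]."""

    mffr: np.ndarray
    vffr: np.ndarray
    threshold: float = 0.80

    def __post_init__(self) -> None:
        self.mffr = np.asarray(self.mffr, dtype=float)
        self.vffr = np.asarray(self.vffr, dtype=float)
        if self.mffr.shape != self.vffr.shape:
            raise ValueError("mFFR and vFFR must have the same length")
        for name, arr in (("mFFR", self.mffr), ("vFFR", self.vffr)):
            if np.any((arr <= 0) | (arr > 1)):
                raise ValueError(f"{name} values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.mffr)


def bland_altman(pairs: PairedFFR) -> dict:
    """Agreement between the two measurements.

    Differences are ``mFFR - vFFR``; the bias is their mean, the limits of
    agreement the bias +/- 2 sample standard deviations.  Returns the
    (mean, difference) points for plotting alongside the summary numbers.
    """
    if len(pairs) < 2:
        raise ValueError("Bland-Altman analysis needs at least 2 pairs")
    d = pairs.mffr - pairs.vffr
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return {
        "bias": bias,
        "sd": sd,
        "limits": (bias - 2.0 * sd, bias + 2.0 * sd),
        "means": 0.5 * (pairs.mffr + pairs.vffr),
        "differences": d,
        "n": len(pairs),
    }


def diagnostic_accuracy(pairs: PairedFFR, threshold: float = 0.80) -> dict:
    """2x2 diagnostic performance of vFFR against measured FFR.

    Positive (ischemic) class: ``mFFR <= threshold``; test positive:
    ``vFFR <= threshold`` (the boundary value counts as positive).  Ratios
    with zero denominators are reported as ``nan`` and listed under
    ``undefined`` rather than silently zeroed.
    """
    if len(pairs) < 1:
        raise ValueError("at least one pair is required")
    truth = pairs.mffr <= threshold
    test = pairs.vffr <= threshold
    tp = int(np.sum(truth & test))
    fn = int(np.sum(truth & ~test))
    fp = int(np.sum(~truth & test))
    tn = int(np.sum(~truth & ~test))

    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    return {
        "sensitivity": ratio(tp, tp + fn, "sensitivity"),
        "specificity": ratio(tn, tn + fp, "specificity"),
        "ppv": ratio(tp, tp + fp, "ppv"),
        "npv": ratio(tn, tn + fn, "npv"),
        "accuracy": (tp + tn) / len(pairs),
        "confusion": {"tp": tp, "fn": fn, "fp": fp, "tn": tn},
        "undefined": undefined,
        "threshold": threshold,
        "n": len(pairs),
    }


def correlation(pairs: PairedFFR) -> dict:
    """Pearson r plus a least-squares line forced through the origin."""
    if len(pairs) < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if np.all(pairs.mffr == pairs.mffr[0]) or np.all(pairs.vffr == pairs.vffr[0]):
        return {"r": math.nan, "slope_through_origin": math.nan, "undefined": ["r"]}
    r, _ = stats.pearsonr(pairs.mffr, pairs.vffr)
    slope = float(np.sum(pairs.mffr * pairs.vffr) / np.sum(pairs.mffr**2))
    return {"r": float(r), "slope_through_origin": slope, "undefined": []}
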