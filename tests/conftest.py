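import numpy as np
import pytest

import stentflow as sf


@pytest.fixture(scope="session")
def bc_default() -> sf.BoundaryConditions:
    """Mean aortic pressure 93 mmHg against the generic distal resistance."""
    return sf.BoundaryConditions.from_mmhg(93.0)


@pytest.fixture(scope="session")
def blood() -> sf.BloodProperties:
    return sf.BloodProperties()


@pytest.fixture()
def straight_tube() -> sf.VesselGeometry:
    """Healthy 50 mm straight tube, radius 1.5 mm, canonical sampling."""
    return sf.make_synthetic_vessel(50.0, 1.5, [])


@pytest.fixture()
def stenosed_vessel() -> sf.VesselGeometry:
    """One mid-vessel 58% diameter stenosis over 20 mm (cohort-typical)."""
    return sf.make_synthetic_vessel(50.0, 1.5, [sf.StenosisSpec(25.0, 20.0, 0.58)])


@pytest.fixture(scope="session")
def small_volume_mesh():
    """Small but fully featured swept mesh for 3D solver tests."""
    vessel = sf.make_synthetic_vessel(10.0, 1.5, [], step=1.0)
    return sf.build_volume_mesh(
        vessel, n_circumferential=12, n_layers=2, target_edge=0.5
    )


def frustum_volume(vessel: sf.VesselGeometry) -> float:
    """Closed-form lumen volume from stacked conical frustums (mm^3)."""
    r = vessel.radii
    ds = np.diff(vessel.s)
    return float(np.sum(np.pi * (r[:-1] ** 2 + r[:-1] * r[1:] + r[1:] ** 2) / 3.0 * ds))
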