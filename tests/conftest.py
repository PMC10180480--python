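import numpy as np
import pytest

from sheetkit.design import FUnitDesign
from sheetkit.synthetic import DistortionParams, generate_funit_snapshot


@pytest.fixture(scope="session")
def default_design():
    return FUnitDesign().with_random_sequences(seed=0)


@pytest.fixture(scope="session")
def funit_ideal(default_design):
    """Noiseless, planar F-unit artifact."""
    return generate_funit_snapshot(default_design, DistortionParams(seed=0))


@pytest.fixture(scope="session")
def funit_tilted(default_design):
    """F-unit with a 30 deg uniform out-of-plane tilt (d_p = 0.5)."""
    return generate_funit_snapshot(
        default_design, DistortionParams(uniform_tilt_deg=30.0, seed=0)
    )


def rigid_transform(snapshot, rng=None, angles=None, shift=None):
    """Apply a global rotation + translation to a snapshot copy."""
    from sheetkit.oxdna import Snapshot

    rng = rng or np.random.default_rng(42)
    if angles is None:
        angles = rng.uniform(0, 2 * np.pi, 3)
    if shift is None:
        shift = rng.uniform(-10, 10, 3)
    ax, ay, az = angles
    rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    rot = rz @ ry @ rx
    return Snapshot(
        time=snapshot.time,
        box=snapshot.box.copy(),
        energies=snapshot.energies.copy(),
        positions=snapshot.positions @ rot.T + shift,
        a1=snapshot.a1 @ rot.T,
        a3=snapshot.a3 @ rot.T,
    )
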