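import numpy as np
import pytest

from celltraction.fields import SubstrateSpec, TractionField
from celltraction.synthetic import _dipole_pair, _render_spots


@pytest.fixture(scope="session")
def substrate() -> SubstrateSpec:
    return SubstrateSpec()


@pytest.fixture(scope="session")
def dipole_field(substrate) -> TractionField:
    """Planted dipole (two antiparallel 1 kPa foci) on a 64-node PIV grid."""
    n = 64
    h = 16 * substrate.pixel_size
    cx = n * h / 2
    foci = _dipole_pair((cx, cx), 24.0, 30.0, 1000.0, 3.0)
    x_um = (np.arange(n) + 0.5) * h
    xx, yy = np.meshgrid(x_um, x_um)
    tx = np.zeros((n, n))
    ty = np.zeros((n, n))
    for f in foci:
        g = np.exp(-((xx - f.center[0]) ** 2 + (yy - f.center[1]) ** 2) / (2 * f.sigma ** 2))
        tx += f.peak_stress * f.direction[0] * g
        ty += f.peak_stress * f.direction[1] * g
    gx = x_um / substrate.pixel_size
    return TractionField(grid_x=gx, grid_y=gx, tx=tx, ty=ty, substrate=substrate)


@pytest.fixture(scope="session")
def bead_pattern():
    """Dense random bead image plus a renderer for shifted copies."""
    rng = np.random.default_rng(7)
    n_beads = 1500
    pos = rng.uniform(0, 256, (n_beads, 2))
    amps = rng.uniform(0.7, 1.3, n_beads)

    def render(shift=(0.0, 0.0)):
        return _render_spots((256, 256), pos + np.asarray(shift), amps, 1.5)

    return render
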