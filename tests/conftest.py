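import numpy as np
import pytest

from aortatlas.core import Centerline
from aortatlas import synthetic as syn

try:
    from hypothesis import settings

    settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
    settings.load_profile("suite")
except ImportError:
    pass


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def cyl():
    """Analytic open cylinder: r = 10 mm, length 60 mm along +z, centred at 0."""
    return syn.cylinder_mesh(10.0, 60.0, n_theta=48, dz=2.0)


@pytest.fixture(scope="session")
def tube_steady():
    """Straight rigid tube with steady Poiseuille flow (v_max = 100 cm/s)."""
    return syn.straight_tube_subject(
        radius=10.0, length=60.0, v_max=100.0, n_phases=5, steady=True
    )


@pytest.fixture(scope="session")
def small_subject():
    """One small synthetic control subject (5 phases, one at the pulse peak)."""
    return syn.make_subject(syn.SubjectSpec(subject_id="c0", seed=42, n_phases=5))


def straight_centerline(length=60.0, z0=-30.0, step=1.0, with_stations=True):
    """Centerline along +z used with the analytic cylinder fixtures."""
    z = np.arange(z0, z0 + length + step / 2, step)
    pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    cl = Centerline(pts)
    if with_stations:
        cl = cl.with_stations(
            {
                "annulus": 0.0,
                "PA_bifurcation": 0.25 * length,
                "brachiocephalic": 0.4 * length,
                "left_subclavian": 0.5 * length,
                "diaphragm": length,
            }
        )
    return cl
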