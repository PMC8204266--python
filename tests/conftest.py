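import numpy as np
import pytest

from ddes.forward_model import (
    AxisymmetricTensor,
    encoding_plane,
    uniform_orientations,
)


@pytest.fixture(scope="session")
def ori256():
    """The default ensemble: 256 Fibonacci-lattice orientations."""
    return uniform_orientations(256)


@pytest.fixture(scope="session")
def plane1():
    return encoding_plane(1)


@pytest.fixture(scope="session")
def quad_powder():
    """Dense deterministic sphere quadrature: the independent powder oracle.

    Gauss-Legendre in the polar cosine times a trapezoid in azimuth
    (120 x 240 = 28800 nodes), evaluated directly from the single-domain
    signal expression -- independent of the Fibonacci-lattice path it checks.
    """
    nz, nph = 120, 240
    z, wz = np.polynomial.legendre.leggauss(nz)
    ph = np.arange(nph) * 2.0 * np.pi / nph
    zz = np.repeat(z, nph)
    pp = np.tile(ph, nz)
    r = np.sqrt(1.0 - zz**2)
    axes = np.column_stack([r * np.cos(pp), r * np.sin(pp), zz])
    w = np.repeat(wz, nph) / (2.0 * nph)

    def integrate(tensor: AxisymmetricTensor, b: float, theta_deg: float, plane):
        e1, e2 = plane
        p1 = axes @ e1
        p2 = axes @ e2
        dd = tensor.d_par - tensor.d_perp
        q1 = tensor.d_perp + dd * p1**2
        q2 = tensor.d_perp + dd * p2**2
        th = np.deg2rad(theta_deg)
        expo = q1 * (1.0 + np.cos(th) ** 2) + q2 * np.sin(th) ** 2
        return float(np.sum(w * np.exp(-0.5e-3 * b * expo)))

    return integrate
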