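"""Angular double-diffusion-encoding (DDE) signals for dispersed tensor ensembles.

The microdomain model is an axially symmetric Gaussian diffusion tensor with
axial diffusivity ``d_par`` and radial diffusivity ``d_perp`` (prolate,
``d_par >= d_perp``).  A DDE experiment applies two diffusion encodings in a
plane spanned by orthonormal vectors ``e1`` and ``e2``; the first encoding is
along ``e1`` and the second along ``cos(theta) e1 + sin(theta) e2``.  For a
single domain rotated so that its symmetry axis points along the unit vector
``u``, the attenuation is::

    S = exp(-b/2 * e1' D' e1) * exp(-b/2 * (cos^2(th) e1' D' e1
                                            + sin^2(th) e2' D' e2))

with ``D' = R D R^T``.  The powder average is the arithmetic mean of this
expression over a set of (approximately) uniformly distributed symmetry axes;
the theta-modulation of that average separates microscopic from macroscopic
anisotropy.

Units
-----
Diffusivities are in um^2/ms and b values in s/mm^2; the product ``b * D`` is
made unitless by the factor 1e-3 (7199 s/mm^2 times 3 um^2/ms gives 21.597).

The default ``variant="no_cross_term"`` evaluates the second-encoding exponent
exactly as the diagonal form above; ``variant="full_quadratic"`` adds the
off-diagonal term ``2 sin(th) cos(th) e1' D' e2`` of the full quadratic form
of the rotated second encoding direction.  After powder averaging the two
agree to Monte-Carlo tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "B_TO_UNITLESS",
    "AxisymmetricTensor",
    "OrientationSet",
    "Compartment",
    "CompartmentMixture",
    "uniform_orientations",
    "encoding_plane",
    "dde_signal_single",
    "powder_signal",
    "powder_signal_curve",
    "mixture_signal",
    "mixture_signal_curve",
]

#: (s/mm^2) * (um^2/ms) -> unitless attenuation exponent
B_TO_UNITLESS = 1e-3

#: Mutually orthogonal first-encoding directions (norm 3/2 before scaling);
#: plane k is spanned by (v_k, v_{k mod 3 + 1}).
_PLANE_TRIPLET = np.array(
    [[1.0, 1.0, -0.5], [-0.5, 1.0, 1.0], [1.0, -0.5, 1.0]]
) / 1.5

_VARIANTS = ("no_cross_term", "full_quadratic")


@dataclass(frozen=True)
class AxisymmetricTensor:
    """Axially symmetric (prolate) microscopic diffusion tensor.

    Parameters
    ----------
    d_par : float
        Axial diffusivity in um^2/ms.
    d_perp : float
        Radial diffusivity in um^2/ms; must satisfy ``0 <= d_perp <= d_par``.
    """

    d_par: float
    d_perp: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d_par) and np.isfinite(self.d_perp)):
            raise ValueError("diffusivities must be finite")
        if not 0.0 <= self.d_perp <= self.d_par:
            raise ValueError(
                f"prolate constraint violated: need d_par >= d_perp >= 0, "
                f"got d_par={self.d_par}, d_perp={self.d_perp}"
            )

    @property
    def mean_diffusivity(self) -> float:
        """MD = (d_par + 2 d_perp) / 3 in um^2/ms."""
        return (self.d_par + 2.0 * self.d_perp) / 3.0

    @classmethod
    def stick(cls, d_par: float) -> "AxisymmetricTensor":
        """Thin-fiber limit: zero radial diffusivity."""
        return cls(d_par, 0.0)

    @classmethod
    def isotropic(cls, d: float) -> "AxisymmetricTensor":
        return cls(d, d)


class OrientationSet:
    """A set of unit vectors: the rotated symmetry axes of a tensor ensemble.

    Each axis is the image of the tensor symmetry axis under one rotation of
    the ensemble; for a powder average the axes should cover the sphere
    (approximately) uniformly.
    """

    def __init__(self, axes: np.ndarray):
        axes = np.atleast_2d(np.asarray(axes, dtype=float))
        if axes.ndim != 2 or axes.shape[1] != 3:
            raise ValueError("axes must be an (n, 3) array")
        norms = np.linalg.norm(axes, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("every axis must be a unit vector")
        self.axes = axes

    @property
    def n(self) -> int:
        return self.axes.shape[0]

    def mean_outer(self) -> np.ndarray:
        """Average outer product of the axes; ~ Identity/3 when uniform."""
        return self.axes.T @ self.axes / self.n

    def to_csv(self, path) -> None:
        np.savetxt(path, self.axes, delimiter=",", header="x,y,z", comments="")


def uniform_orientations(
    n: int, method: str = "fibonacci", seed: int | None = None
) -> OrientationSet:
    """Generate ``n`` approximately uniform unit vectors on the sphere.

    ``method="fibonacci"`` returns the deterministic Fibonacci-sphere lattice
    (low discrepancy, reproducible); ``method="random"`` draws isotropically
    at random, reproducibly for a fixed ``seed``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if method == "fibonacci":
        i = np.arange(n)
        z = 1.0 - (2.0 * i + 1.0) / n
        golden = np.pi * (3.0 - np.sqrt(5.0))
        phi = golden * i
        r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
        axes = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    elif method == "random":
        rng = np.random.default_rng(seed)
        axes = rng.standard_normal((n, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown method {method!r}")
    return OrientationSet(axes)


def encoding_plane(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis (e1, e2) of encoding plane ``k`` in {1, 2, 3}.

    e1 is the fixed first-encoding direction of the plane; the second encoding
    revolves in the (e1, e2) plane.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"plane index must be 1, 2 or 3, got {k}")
    return _PLANE_TRIPLET[k - 1].copy(), _PLANE_TRIPLET[k % 3].copy()


def _check_plane(plane: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    e1 = np.asarray(plane[0], dtype=float)
    e2 = np.asarray(plane[1], dtype=float)
    if (
        abs(np.linalg.norm(e1) - 1.0) > 1e-8
        or abs(np.linalg.norm(e2) - 1.0) > 1e-8
        or abs(float(e1 @ e2)) > 1e-8
    ):
        raise ValueError("plane must be a pair of orthonormal vectors")
    return e1, e2


def _attenuation(
    b: np.ndarray,
    theta_deg: np.ndarray,
    p1: np.ndarray,
    p2: np.ndarray,
    d_par: float,
    d_perp: float,
    variant: str,
) -> np.ndarray:
    """Powder-averaged attenuation for (b, theta) arrays.

    ``p1``, ``p2`` are the projections of the ensemble axes on (e1, e2).
    Returns the mean over axes, shape ``b.shape``.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {_VARIANTS}, got {variant!r}")
    dd = d_par - d_perp
    q1 = d_perp + dd * p1 * p1
    q2 = d_perp + dd * p2 * p2
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    expo = q1[None, :] * (1.0 + c * c)[:, None] + q2[None, :] * (s * s)[:, None]
    if variant == "full_quadratic":
        expo = expo + (2.0 * s * c)[:, None] * (dd * p1 * p2)[None, :]
    return np.exp(-0.5 * B_TO_UNITLESS * b[:, None] * expo).mean(axis=1)


def dde_signal_single(
    tensor: AxisymmetricTensor,
    axis: np.ndarray,
    b: float,
    theta: float,
    plane: Sequence[np.ndarray],
    variant: str = "no_cross_term",
) -> float:
    """DDE attenuation of one domain whose symmetry axis is ``axis``.

    ``axis`` is the rotated symmetry-axis unit vector (the rotation applied
    to the tensor).  Returns a unitless attenuation in (0, 1].
    """
    if b < 0:
        raise ValueError("b must be >= 0")
    e1, e2 = _check_plane(plane)
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
        raise ValueError("axis must be a unit vector")
    p1 = np.array([axis @ e1])
    p2 = np.array([axis @ e2])
    out = _attenuation(
        np.array([float(b)]), np.array([float(theta)]), p1, p2,
        tensor.d_par, tensor.d_perp, variant,
    )
    return float(out[0])


def powder_signal_curve(
    tensor: AxisymmetricTensor,
    orientations: OrientationSet,
    b,
    theta,
    plane: Sequence[np.ndarray],
    s0: float = 1.0,
    variant: str = "no_cross_term",
) -> np.ndarray:
    """Vectorized powder-averaged signal for broadcastable (b, theta) arrays."""
    e1, e2 = _check_plane(plane)
    b_arr, th_arr = np.broadcast_arrays(
        np.atleast_1d(np.asarray(b, dtype=float)),
        np.atleast_1d(np.asarray(theta, dtype=float)),
    )
    if np.any(b_arr < 0):
        raise ValueError("b must be >= 0")
    p1 = orientations.axes @ e1
    p2 = orientations.axes @ e2
    return s0 * _attenuation(
        b_arr.ravel(), th_arr.ravel(), p1, p2,
        tensor.d_par, tensor.d_perp, variant,
    ).reshape(b_arr.shape)


def powder_signal(
    tensor: AxisymmetricTensor,
    orientations: OrientationSet,
    b: float,
    theta: float,
    plane: Sequence[np.ndarray],
    s0: float = 1.0,
    variant: str = "no_cross_term",
) -> float:
    """Powder-averaged DDE signal: s0 times the mean single-domain attenuation."""
    return float(
        powder_signal_curve(tensor, orientations, b, theta, plane, s0, variant)[0]
    )


@dataclass(frozen=True)
class Compartment:
    label: str
    fraction: float
    tensor: AxisymmetricTensor


class CompartmentMixture:
    """Signal-fraction-weighted mixture of axisymmetric compartments.

    Fractions are signal fractions at b = 0 and must be non-negative and sum
    to 1.  Typical brain-water use: an intracellular "stick-like" compartment,
    an extracellular tensor, and isotropic CSF at the free-water diffusivity.
    """

    def __init__(self, compartments: Iterable[Compartment | tuple]):
        comps = []
        for c in compartments:
            if not isinstance(c, Compartment):
                c = Compartment(*c)
            comps.append(c)
        if not comps:
            raise ValueError("mixture must contain at least one compartment")
        fractions = np.array([c.fraction for c in comps], dtype=float)
        if np.any(fractions < 0):
            raise ValueError("fractions must be >= 0")
        if abs(fractions.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"fractions must sum to 1, got {fractions.sum():.12g}"
            )
        self.compartments: tuple[Compartment, ...] = tuple(comps)

    def __iter__(self):
        return iter(self.compartments)

    def __len__(self) -> int:
        return len(self.compartments)


def mixture_signal_curve(
    mixture: CompartmentMixture,
    orientations: OrientationSet,
    b,
    theta,
    plane: Sequence[np.ndarray],
    s0: float = 1.0,
    variant: str = "no_cross_term",
) -> np.ndarray:
    """Fraction-weighted sum of per-compartment powder signals (vectorized)."""
    out = None
    for comp in mixture:
        term = comp.fraction * powder_signal_curve(
            comp.tensor, orientations, b, theta, plane, s0, variant
        )
        out = term if out is None else out + term
    return out


def mixture_signal(
    mixture: CompartmentMixture,
    orientations: OrientationSet,
    b: float,
    theta: float,
    plane: Sequence[np.ndarray],
    s0: float = 1.0,
    variant: str = "no_cross_term",
) -> float:
    """Mixture powder signal at a single (b, theta); equals s0 at b = 0."""
    return float(
        mixture_signal_curve(mixture, orientations, b, theta, plane, s0, variant)[0]
    )
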