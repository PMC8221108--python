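"""Independent oracles used by the test suite.

These deliberately do not share code with the package: exact rational
arithmetic (fractions) and arbitrary-precision decimal arithmetic for
the shape formulas, and the Legendre elliptic-integral closed form for
the surface area of a triaxial ellipsoid.
"""

from __future__ import annotations

from decimal import Decimal, getcontext
from fractions import Fraction

import numpy as np
from scipy.special import ellipeinc, ellipkinc

#: π to 50 decimal places (for the arbitrary-precision sphericity oracle).
PI_50 = Decimal("3.14159265358979323846264338327950288419716939937510")


def frac_prolate(a: Fraction, b: Fraction, c: Fraction) -> Fraction:
    """Prolate ellipticity evaluated exactly over the rationals."""
    return (2 * a * a / (a * a + b * b)) * (1 - (a * a + b * b) / (2 * c * c))


def frac_oblate(a: Fraction, b: Fraction, c: Fraction) -> Fraction:
    """Oblate ellipticity evaluated exactly over the rationals."""
    return (2 * b * b / (b * b + c * c)) * (1 - 2 * a * a / (b * b + c * c))


def dec_sphericity(volume: Fraction, area: Fraction, prec: int = 50) -> Decimal:
    """Wadell sphericity at `prec` significant digits via decimal arithmetic."""
    getcontext().prec = prec
    v = Decimal(volume.numerator) / Decimal(volume.denominator)
    a = Decimal(area.numerator) / Decimal(area.denominator)
    third = Decimal(1) / Decimal(3)
    return PI_50**third * (6 * v) ** (2 * third) / a


def ellipsoid_surface_area(a: float, b: float, c: float) -> float:
    """Exact surface area of a triaxial ellipsoid (Legendre form)."""
    a, b, c = sorted([a, b, c], reverse=True)
    if np.isclose(a, c):
        return float(4 * np.pi * a * a)
    phi = np.arccos(c / a)
    k2 = (a * a * (b * b - c * c)) / (b * b * (a * a - c * c))
    F = ellipkinc(phi, k2)
    E = ellipeinc(phi, k2)
    s = np.sin(phi)
    return float(2 * np.pi * c * c + 2 * np.pi * a * b / s * (E * s * s + F * np.cos(phi) ** 2))


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    return float(4.0 / 3.0 * np.pi * a * b * c)


def ellipsoid_sphericity(a: float, b: float, c: float) -> float:
    """Analytic Wadell sphericity of a triaxial ellipsoid."""
    v = ellipsoid_volume(a, b, c)
    s = ellipsoid_surface_area(a, b, c)
    return float(np.pi ** (1 / 3) * (6 * v) ** (2 / 3) / s)


def rasterize_ellipsoid_mask(
    semi_axes,
    voxel_size,
    rotation: np.ndarray | None = None,
    pad_um: float = 2.0,
) -> np.ndarray:
    """Voxelize one centered solid ellipsoid (independent of the package)."""
    vs = np.asarray(voxel_size, dtype=float)
    r = max(semi_axes) + pad_um
    shape = tuple(int(np.ceil(2 * r / v)) for v in vs)
    zz, yy, xx = np.indices(shape)
    coords = np.stack([zz * vs[0], yy * vs[1], xx * vs[2]], axis=-1)
    center = np.array([(s - 1) * v / 2 for s, v in zip(shape, vs)])
    d = coords - center
    if rotation is not None:
        d = d @ rotation.T
    q = np.sum((d / np.asarray(semi_axes, dtype=float)) ** 2, axis=-1)
    return q <= 1.0
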