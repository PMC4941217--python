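"""Elementary vector geometry shared by every classifier.

All functions take Cartesian coordinates in Angstrom (any array-like of
length 3) and return distances in Angstrom or angles in degrees. Dihedrals
are reported as magnitudes in [0, 180] because every screening threshold
that consumes them is one-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

NOT_MEASURED = float("nan")


class DegenerateGeometryError(ValueError):
    """Raised when an angle/dihedral/plane is requested for coincident or
    collinear points."""


@dataclass
class GeometricMeasurement:
    """Geometric parameters attached to a classified interaction.

    Fields that a given interaction type does not measure stay NaN.

    d : H...O or O...C distance (A)
    omega : donor angle heavy-H...O (deg)
    rho : acceptor angle H...O=C (deg)
    theta : O...C=O approach angle for n->pi* (deg)
    chi : planarity dihedral magnitude for n->pi* (deg)
    elevation : out-of-carbonyl-plane angle of a C-H donor hydrogen (deg)
    """

    d: float = NOT_MEASURED
    omega: float = NOT_MEASURED
    rho: float = NOT_MEASURED
    theta: float = NOT_MEASURED
    chi: float = NOT_MEASURED
    elevation: float = NOT_MEASURED

    def as_dict(self) -> dict:
        return {
            "d": self.d,
            "omega": self.omega,
            "rho": self.rho,
            "theta": self.theta,
            "chi": self.chi,
            "elevation": self.elevation,
        }


def _vec(a) -> np.ndarray:
    return np.asarray(a, dtype=float)


def distance(a, b) -> float:
    """Euclidean distance between two points (A)."""
    return float(np.linalg.norm(_vec(a) - _vec(b)))


def angle(a, b, c) -> float:
    """Angle a-b-c at vertex b, in degrees in [0, 180]."""
    u = _vec(a) - _vec(b)
    v = _vec(c) - _vec(b)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-10 or nv < 1e-10:
        raise DegenerateGeometryError("zero-length arm in angle()")
    cosang = float(np.dot(u, v) / (nu * nv))
    cosang = max(-1.0, min(1.0, cosang))
    return math.degrees(math.acos(cosang))


def dihedral(a, b, c, d) -> float:
    """Magnitude of the torsion angle a-b-c-d about the b-c axis, degrees in
    [0, 180]."""
    return abs(signed_dihedral(a, b, c, d))


def signed_dihedral(a, b, c, d) -> float:
    """Signed torsion a-b-c-d in (-180, 180], IUPAC convention (cis = 0,
    trans = 180; positive = clockwise rotation of the far bond viewed from
    b towards c)."""
    b0 = _vec(a) - _vec(b)
    b1 = _vec(c) - _vec(b)
    b2 = _vec(d) - _vec(c)
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-10:
        raise DegenerateGeometryError("coincident axis atoms in dihedral()")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise DegenerateGeometryError("collinear arm in dihedral()")
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    return math.degrees(math.atan2(y, x))


def plane_normal(p1, p2, p3) -> np.ndarray:
    """Unit normal of the plane through three points."""
    u = _vec(p2) - _vec(p1)
    v = _vec(p3) - _vec(p1)
    n = np.cross(u, v)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise DegenerateGeometryError("collinear plane atoms")
    return n / norm


def elevation(p, plane_atoms, reference=None) -> float:
    """Elevation of point ``p`` above the plane of three atoms, in degrees.

    The angle is measured between the vector from ``reference`` (by default
    the first plane atom) to ``p`` and the plane itself: 0 deg means the
    point lies in the plane, 90 deg means it sits on the plane normal. Used
    to restrict the out-of-plane approach of C-H donors to the sp2 carbonyl
    plane, where ``reference`` is the acceptor oxygen.
    """
    p1, p2, p3 = plane_atoms
    n = plane_normal(p1, p2, p3)
    ref = _vec(p1) if reference is None else _vec(reference)
    v = _vec(p) - ref
    nv = np.linalg.norm(v)
    if nv < 1e-10:
        raise DegenerateGeometryError("point coincides with reference")
    sin_elev = abs(float(np.dot(v, n)) / nv)
    sin_elev = min(1.0, sin_elev)
    return math.degrees(math.asin(sin_elev))
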