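"""Triclinic periodic box with minimum-image operations.

The box is a 3x3 matrix whose *rows* are the box vectors a, b, c in nm,
stored in the Gromacs lower-triangular convention: a along +x, b in the
xy-plane.  Arbitrary input boxes are rotated into this convention on
construction, which makes the representation unique.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import FormatError

__all__ = ["PeriodicBox", "box_wrap_vector"]

# the 27 integer lattice shifts used for triclinic minimum-image searches
_SHIFTS = np.array(
    [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
    dtype=float,
)


class PeriodicBox:
    """A valid (positive-volume) periodic box in lower-triangular form."""

    __slots__ = ("matrix", "_inv", "_ortho")

    def __init__(self, matrix) -> None:
        m = np.asarray(matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("box matrix must be 3x3")
        if not np.all(np.isfinite(m)):
            raise ValueError("box matrix contains non-finite values")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("degenerate box: volume <= 0")
        if m[0, 1] or m[0, 2] or m[1, 2]:
            m = _to_lower_triangular(m)
        if np.linalg.det(m) <= 0:
            # a left-handed row set: flip c to restore positive volume
            m = m.copy()
            m[2] = -m[2]
            m = _to_lower_triangular(m)
        self.matrix = m
        self._inv = np.linalg.inv(m)
        self._ortho = bool(abs(m[1, 0]) < 1e-12 and abs(m[2, 0]) < 1e-12
                           and abs(m[2, 1]) < 1e-12)

    # -- constructors -------------------------------------------------
    @classmethod
    def cubic(cls, edge: float) -> "PeriodicBox":
        return cls(np.eye(3) * float(edge))

    @classmethod
    def from_lengths_angles(cls, a, b, c, alpha, beta, gamma) -> "PeriodicBox":
        """Build from edge lengths (nm) and angles (degrees)."""
        al, be, ga = (math.radians(x) for x in (alpha, beta, gamma))
        ax = a
        bx, by = b * math.cos(ga), b * math.sin(ga)
        cx = c * math.cos(be)
        cy = c * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
        cz_sq = c * c - cx * cx - cy * cy
        if cz_sq <= 0:
            raise ValueError("inconsistent box lengths/angles")
        m = np.array([[ax, 0.0, 0.0], [bx, by, 0.0], [cx, cy, math.sqrt(cz_sq)]])
        return cls(m)

    def to_lengths_angles(self) -> tuple[float, float, float, float, float, float]:
        a, b, c = self.matrix
        la, lb, lc = (float(np.linalg.norm(v)) for v in (a, b, c))
        alpha = math.degrees(math.acos(np.dot(b, c) / (lb * lc)))
        beta = math.degrees(math.acos(np.dot(a, c) / (la * lc)))
        gamma = math.degrees(math.acos(np.dot(a, b) / (la * lb)))
        return la, lb, lc, alpha, beta, gamma

    # -- geometry -----------------------------------------------------
    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.matrix)))

    @property
    def is_orthorhombic(self) -> bool:
        return self._ortho

    def heights(self) -> np.ndarray:
        """Perpendicular widths of the cell along each axis pair (nm)."""
        a, b, c = self.matrix
        v = self.volume
        return np.array([
            v / np.linalg.norm(np.cross(b, c)),
            v / np.linalg.norm(np.cross(c, a)),
            v / np.linalg.norm(np.cross(a, b)),
        ])

    def to_fractional(self, r: np.ndarray) -> np.ndarray:
        return np.asarray(r, dtype=float) @ self._inv

    def to_cartesian(self, f: np.ndarray) -> np.ndarray:
        return np.asarray(f, dtype=float) @ self.matrix

    def min_image(self, d: np.ndarray) -> np.ndarray:
        """Minimum-image representative(s) of displacement vector(s) ``d``.

        Exact for orthorhombic boxes; for triclinic boxes the 27 neighbor
        lattice translations around the rounded image are searched.
        """
        d = np.asarray(d, dtype=float)
        single = d.ndim == 1
        d2 = np.atleast_2d(d)
        f = d2 @ self._inv
        f -= np.round(f)
        cart = f @ self.matrix
        if not self._ortho:
            # candidate images: cart + shift @ matrix for the 27 shifts
            cands = cart[:, None, :] + (_SHIFTS @ self.matrix)[None, :, :]
            best = np.argmin(np.einsum("ijk,ijk->ij", cands, cands), axis=1)
            cart = cands[np.arange(len(cands)), best]
        return cart[0] if single else cart

    def wrap_points(self, r: np.ndarray) -> np.ndarray:
        """Map points into the primary cell (fractional coords in [0, 1))."""
        f = np.mod(self.to_fractional(r), 1.0)
        f[f >= 1.0] = 0.0  # guard against 1.0 from rounding of tiny negatives
        return self.to_cartesian(f)

    def __eq__(self, other) -> bool:
        return isinstance(other, PeriodicBox) and np.allclose(self.matrix, other.matrix)

    def __repr__(self) -> str:
        la, lb, lc, al, be, ga = self.to_lengths_angles()
        return (f"PeriodicBox(a={la:.4f}, b={lb:.4f}, c={lc:.4f} nm, "
                f"alpha={al:.2f}, beta={be:.2f}, gamma={ga:.2f})")


def _to_lower_triangular(m: np.ndarray) -> np.ndarray:
    """Rotate a row-vector box into the a-along-x, b-in-xy convention."""
    a, b, c = m
    la = np.linalg.norm(a)
    lb = np.linalg.norm(b)
    lc = np.linalg.norm(c)
    if min(la, lb, lc) < 1e-12:
        raise ValueError("degenerate box vector")
    cos_g = np.dot(a, b) / (la * lb)
    cos_b = np.dot(a, c) / (la * lc)
    cos_a = np.dot(b, c) / (lb * lc)
    sin_g = math.sqrt(max(0.0, 1.0 - cos_g * cos_g))
    out = np.zeros((3, 3))
    out[0, 0] = la
    out[1, 0] = lb * cos_g
    out[1, 1] = lb * sin_g
    out[2, 0] = lc * cos_b
    out[2, 1] = lc * (cos_a - cos_b * cos_g) / sin_g
    cz_sq = lc * lc - out[2, 0] ** 2 - out[2, 1] ** 2
    if cz_sq <= 0:
        raise ValueError("degenerate box after rotation")
    out[2, 2] = math.sqrt(cz_sq)
    return out


def box_wrap_vector(box: PeriodicBox, d) -> np.ndarray:
    """Functional alias for :meth:`PeriodicBox.min_image` on one vector."""
    if not isinstance(box, PeriodicBox):
        raise FormatError("box_wrap_vector requires a valid PeriodicBox")
    return box.min_image(np.asarray(d, dtype=float))
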