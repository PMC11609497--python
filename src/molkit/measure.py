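"""Read-only geometric measures: centers, RMSD, Kabsch fitting, gyration, SASA.

All lengths are nm, masses amu, areas nm^2.  Functions accept either a
:class:`~molkit.selections.Selection` or a plain coordinate array (with
masses supplied explicitly where needed), so the same code path serves the
selection API and low-level callers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .box import PeriodicBox
from .elements import vdw_radius_of
from .errors import MolkitError
from .neighbor import neighbor_lists

__all__ = [
    "RigidTransform", "center_of_mass", "center_of_geometry", "rmsd",
    "fit_transform", "kabsch", "radius_of_gyration", "sasa",
]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation (det = +1) followed by a translation.

    Applies to a point as ``r' = R @ r + t``; for row-stacked coordinate
    arrays use :meth:`apply`.
    """

    rotation: np.ndarray   # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3, translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is a reflection (det < 0)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def translation_only(cls, v) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(v, dtype=float))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


def _coords_masses(sel, masses=None):
    if hasattr(sel, "coords") and hasattr(sel, "masses") and not isinstance(sel, np.ndarray):
        return sel.coords, (sel.masses if masses is None else np.asarray(masses, float))
    coords = np.asarray(sel, dtype=float)
    m = np.ones(len(coords)) if masses is None else np.asarray(masses, float)
    return coords, m


def _weighted_center(coords, weights, box: Optional[PeriodicBox], pbc: bool):
    wsum = weights.sum()
    if wsum <= 0:
        raise MolkitError("total weight is zero; cannot compute a weighted center")
    if not pbc:
        return (weights[:, None] * coords).sum(axis=0) / wsum
    if box is None:
        raise MolkitError("pbc=True requires a periodic box")
    # per-axis circular mean in fractional space: average unit vectors on
    # the circle, map the mean angle back to a fractional coordinate
    frac = box.to_fractional(coords)
    theta = 2.0 * math.pi * frac
    c = (weights[:, None] * np.cos(theta)).sum(axis=0)
    s = (weights[:, None] * np.sin(theta)).sum(axis=0)
    mean_theta = np.arctan2(s, c)
    f = np.mod(mean_theta / (2.0 * math.pi), 1.0)
    return box.to_cartesian(f)


def center_of_mass(sel, pbc: bool = False, box: Optional[PeriodicBox] = None,
                   masses=None) -> np.ndarray:
    """Mass-weighted center (nm).

    With ``pbc=True`` the center is computed per box axis as a circular
    mean, so a cluster wrapped across a boundary gets a center inside the
    cluster rather than in the middle of the box.  Meaningful only for
    clusters smaller than about half the box.
    """
    coords, m = _coords_masses(sel, masses)
    if box is None and hasattr(sel, "box") and not isinstance(sel, np.ndarray):
        box = sel.box
    return _weighted_center(coords, m, box, pbc)


def center_of_geometry(sel, pbc: bool = False,
                       box: Optional[PeriodicBox] = None) -> np.ndarray:
    """Unweighted center: :func:`center_of_mass` with unit masses."""
    coords, _ = _coords_masses(sel)
    if box is None and hasattr(sel, "box") and not isinstance(sel, np.ndarray):
        box = sel.box
    return _weighted_center(coords, np.ones(len(coords)), box, pbc)


def rmsd(a, b) -> float:
    """Plain RMSD (nm) between positionally paired atoms; no fitting."""
    ca, _ = _coords_masses(a)
    cb, _ = _coords_masses(b)
    if ca.shape != cb.shape:
        raise MolkitError(f"size mismatch: {ca.shape[0]} vs {cb.shape[0]} atoms")
    if len(ca) == 0:
        raise MolkitError("rmsd of empty selections")
    d = ca - cb
    return float(np.sqrt(np.einsum("ij,ij->", d, d) / len(ca)))


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           weights: Optional[np.ndarray] = None) -> RigidTransform:
    """Optimal proper superposition of ``mobile`` onto ``reference``.

    Covariance SVD with determinant correction: when the best orthogonal
    map is a reflection, the sign of the smallest singular direction is
    flipped so the returned rotation always has det = +1.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape:
        raise MolkitError(f"size mismatch: {P.shape[0]} vs {Q.shape[0]} atoms")
    if len(P) < 3:
        raise MolkitError("fitting needs at least 3 atoms")
    w = np.ones(len(P)) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    if wsum <= 0:
        raise MolkitError("total weight is zero")
    cp = (w[:, None] * P).sum(axis=0) / wsum
    cq = (w[:, None] * Q).sum(axis=0) / wsum
    H = (w[:, None] * (P - cp)).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return RigidTransform(R, t)


def fit_transform(mobile, reference, mass_weighted: bool = True) -> RigidTransform:
    """Kabsch fit of a mobile selection onto a reference selection."""
    cm, mm = _coords_masses(mobile)
    cr, _ = _coords_masses(reference)
    weights = mm if mass_weighted else None
    return kabsch(cm, cr, weights)


def radius_of_gyration(sel, mass_weighted: bool = True, masses=None) -> float:
    """sqrt(sum w |r - c|^2 / sum w) with c the matching weighted center."""
    coords, m = _coords_masses(sel, masses)
    w = m if mass_weighted else np.ones(len(coords))
    wsum = w.sum()
    if wsum <= 0:
        raise MolkitError("total weight is zero")
    c = (w[:, None] * coords).sum(axis=0) / wsum
    d2 = np.einsum("ij,ij->i", coords - c, coords - c)
    return float(np.sqrt((w * d2).sum() / wsum))


def _golden_spiral(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(sel, probe_radius: float = 0.14, n_points: int = 960,
         radii=None) -> tuple[np.ndarray, float]:
    """Solvent accessible surface area by Shrake-Rupley quadrature.

    Each atom gets ``n_points`` quasi-uniform test points on its expanded
    sphere (vdW radius + probe); a point is exposed when outside every
    neighbor's expanded sphere.  Returns (per-atom areas, total) in nm^2.
    Periodic images are ignored: SASA is evaluated on the coordinates as
    given, which assumes a whole (unwrapped) molecule.

    Raises when an atom's element has no tabulated vdW radius and no
    explicit ``radii`` are passed.
    """
    if hasattr(sel, "atoms") and not isinstance(sel, np.ndarray):
        coords = sel.coords
        if radii is None:
            radii = []
            for k, atom in enumerate(sel.atoms()):
                r = vdw_radius_of(atom.element)
                if r is None:
                    raise MolkitError(
                        f"no van-der-Waals radius for atom {k} "
                        f"({atom.name!r}, element {atom.element!r})")
                radii.append(r)
    else:
        coords = np.asarray(sel, dtype=float)
        if radii is None:
            raise MolkitError("explicit radii are required for bare coordinates")
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise MolkitError("all van-der-Waals radii must be positive")
    expanded = radii + probe_radius
    n = len(coords)
    unit = _golden_spiral(n_points)
    cutoff = 2.0 * float(expanded.max())
    neighbors = neighbor_lists(coords, cutoff)
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        nb = neighbors[i]
        # drop neighbors that cannot bury any point of this sphere
        if nb.size:
            d = np.linalg.norm(coords[nb] - coords[i], axis=1)
            nb = nb[d < expanded[i] + expanded[nb]]
        exposed = np.ones(n_points, dtype=bool)
        for j in nb:
            dj = pts - coords[j]
            exposed &= np.einsum("ij,ij->i", dj, dj) > expanded[j] ** 2
            if not exposed.any():
                break
        areas[i] = exposed.mean() * 4.0 * math.pi * expanded[i] ** 2
    return areas, float(areas.sum())
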