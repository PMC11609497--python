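"""Distance queries via a cell list, with and without periodic boundaries.

The grid bins atoms into cells whose edge (measured as a perpendicular
height for triclinic boxes) is at least the cutoff, so that scanning the 27
cells around a query atom's cell finds every candidate within the cutoff.
When a periodic box is too small for that assumption (cutoff larger than
half the smallest box height) the search falls back to a brute-force
minimum-image scan with a logged warning.

Ties at exactly the cutoff are included (<= comparison on squared
distances).
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np

from .box import PeriodicBox

__all__ = ["CellGrid", "search_within", "neighbor_lists"]

log = logging.getLogger(__name__)


class CellGrid:
    """Spatial hash of points into cells of edge >= cutoff.

    For periodic systems the grid lives in fractional space and cell indices
    wrap; for aperiodic systems it covers the bounding box and clamps.
    """

    def __init__(self, coords: np.ndarray, cutoff: float,
                 box: Optional[PeriodicBox] = None) -> None:
        coords = np.asarray(coords, dtype=float)
        self.coords = coords
        self.box = box
        self.periodic = box is not None
        n = len(coords)
        if self.periodic:
            heights = box.heights()
            dims = np.maximum(1, np.floor(heights / cutoff).astype(int))
            frac = np.mod(box.to_fractional(coords), 1.0)
            cells = np.minimum((frac * dims).astype(int), dims - 1)
        else:
            lo = coords.min(axis=0) if n else np.zeros(3)
            hi = coords.max(axis=0) if n else np.ones(3)
            span = np.maximum(hi - lo, 1e-9)
            dims = np.maximum(1, np.minimum(np.floor(span / cutoff).astype(int), 64))
            cells = np.minimum(((coords - lo) / span * dims).astype(int), dims - 1)
            self._lo, self._span = lo, span
        self.dims = dims
        self.cell_of = cells  # (n, 3) integer cell per atom
        flat = np.ravel_multi_index(cells.T, dims)
        order = np.argsort(flat, kind="stable")
        self._sorted_atoms = order
        self._sorted_flat = flat[order]

    def atoms_in_cell(self, cell: np.ndarray) -> np.ndarray:
        flat = np.ravel_multi_index(np.asarray(cell) % self.dims
                                    if self.periodic else np.asarray(cell), self.dims)
        lo = np.searchsorted(self._sorted_flat, flat, side="left")
        hi = np.searchsorted(self._sorted_flat, flat, side="right")
        return self._sorted_atoms[lo:hi]

    def neighborhood(self, cell: np.ndarray) -> np.ndarray:
        """Atom indices in the 27 cells around ``cell`` (deduplicated)."""
        cell = np.asarray(cell)
        seen: set[int] = set()
        chunks = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    c = cell + (dx, dy, dz)
                    if self.periodic:
                        c = c % self.dims
                    elif np.any(c < 0) or np.any(c >= self.dims):
                        continue
                    key = int(np.ravel_multi_index(c, self.dims))
                    if key in seen:
                        continue
                    seen.add(key)
                    chunks.append(self.atoms_in_cell(c))
        if not chunks:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(chunks)


def _displacements(coords_a, coords_b, box):
    """Pairwise displacement (a_i - b_j) with minimum image when boxed."""
    d = coords_a[:, None, :] - coords_b[None, :, :]
    if box is not None:
        flat = box.min_image(d.reshape(-1, 3))
        d = flat.reshape(d.shape)
    return d


def _brute_force_within(coords, query, cutoff, box):
    hits = np.zeros(len(coords), dtype=bool)
    qc = coords[query]
    # chunk over all atoms to bound memory
    step = max(1, int(2_000_000 / max(1, len(query))))
    for start in range(0, len(coords), step):
        block = coords[start:start + step]
        d = _displacements(block, qc, box)
        dist2 = np.einsum("ijk,ijk->ij", d, d)
        hits[start:start + step] = (dist2 <= cutoff * cutoff).any(axis=1)
    return hits


def search_within(coords: np.ndarray, query, cutoff: float,
                  box: Optional[PeriodicBox] = None,
                  include_query: bool = True) -> np.ndarray:
    """Indices of all atoms within ``cutoff`` (nm) of any query atom.

    Distances are minimum-image when ``box`` is given.  Query atoms are part
    of the result by construction (they are at distance 0 of themselves);
    with ``include_query=False`` the query set is removed from the result.

    Returns a sorted, unique int64 index array.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    coords = np.asarray(coords, dtype=float)
    query = np.asarray(query, dtype=np.int64)
    if query.size == 0:
        return np.empty(0, dtype=np.int64)
    cutoff2 = cutoff * cutoff

    if box is not None and cutoff > 0.5 * float(box.heights().min()):
        log.warning("cutoff %.3f nm exceeds half the smallest box height; "
                    "falling back to brute-force minimum-image search", cutoff)
        hits = _brute_force_within(coords, query, cutoff, box)
    else:
        grid = CellGrid(coords, cutoff, box)
        hits = np.zeros(len(coords), dtype=bool)
        # group query atoms by cell so each neighborhood is gathered once
        qcells = grid.cell_of[query]
        qflat = np.ravel_multi_index(qcells.T, grid.dims)
        order = np.argsort(qflat, kind="stable")
        start = 0
        while start < len(query):
            end = start
            while end < len(query) and qflat[order[end]] == qflat[order[start]]:
                end += 1
            members = query[order[start:end]]
            cand = grid.neighborhood(grid.cell_of[members[0]])
            if cand.size:
                d = _displacements(coords[cand], coords[members], box)
                dist2 = np.einsum("ijk,ijk->ij", d, d)
                hits[cand] |= (dist2 <= cutoff2).any(axis=1)
            start = end
    hits[query] = include_query
    return np.flatnonzero(hits).astype(np.int64)


def neighbor_lists(coords: np.ndarray, cutoff: float,
                   box: Optional[PeriodicBox] = None) -> list[np.ndarray]:
    """Per-atom neighbor lists (all pairs within ``cutoff``, self excluded)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    grid = CellGrid(coords, cutoff, box)
    cutoff2 = cutoff * cutoff
    out: list[np.ndarray] = []
    for i in range(n):
        cand = grid.neighborhood(grid.cell_of[i])
        cand = cand[cand != i]
        if cand.size:
            d = coords[cand] - coords[i]
            if box is not None:
                d = box.min_image(d)
            dist2 = np.einsum("ij,ij->i", d, d)
            cand = cand[dist2 <= cutoff2]
        out.append(np.sort(cand))
    return out
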