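"""Read-write operations on selections: rigid transforms, wrapping, unwrapping."""

from __future__ import annotations

import numpy as np

from .errors import MolkitError
from .measure import RigidTransform

__all__ = ["apply_transform", "translate", "wrap", "unwrap"]


def apply_transform(sel, t: RigidTransform) -> None:
    """Apply ``r := R r + t`` to every selected atom; others untouched."""
    sel.set_coords(t.apply(sel.coords))


def translate(sel, v) -> None:
    """Shift every selected atom by ``v`` (nm)."""
    apply_transform(sel, RigidTransform.translation_only(v))


def wrap(sel) -> None:
    """Map the selected atoms into the primary cell (fractional [0, 1))."""
    box = sel.box
    if box is None:
        raise MolkitError("wrap requires a periodic box")
    sel.set_coords(box.wrap_points(sel.coords))


def unwrap(sel, anchor: int = 0) -> None:
    """Remove periodic jumps along the selection's index order.

    Starting from the ``anchor``-th selected atom, each atom is moved to the
    periodic image closest to its predecessor in the selection (chain rule;
    atoms before the anchor are chained backwards).  Uses index order, not
    bonds, so branched molecules whose index order jumps spatially may not
    be made whole.
    """
    box = sel.box
    if box is None:
        raise MolkitError("unwrap requires a periodic box")
    coords = sel.coords
    n = len(coords)
    if not 0 <= anchor < n:
        raise MolkitError(f"anchor {anchor} out of range for {n} selected atoms")
    diffs = box.min_image(np.diff(coords, axis=0)) if n > 1 else np.zeros((0, 3))
    out = np.empty_like(coords)
    out[anchor] = coords[anchor]
    for i in range(anchor + 1, n):
        out[i] = out[i - 1] + diffs[i - 1]
    for i in range(anchor - 1, -1, -1):
        out[i] = out[i + 1] - diffs[i]
    sel.set_coords(out)
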