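"""Core data model: Atom, Topology, State, access kinds and the System container.

A :class:`System` pairs one Topology with one State and fixes an
:class:`AccessKind` that every selection created from it inherits.  The kind
is an access contract (Table below) fixed at construction:

=================  ==========  ============  =======================
kind               data access  may overlap?  validity check required
=================  ==========  ============  =======================
MutableSerial      read/write   yes           no
BuilderSerial      read/write   yes           yes (structural edits)
ImmutableParallel  read only    yes           no
MutableParallel    read/write   no            no
=================  ==========  ============  =======================

Passing a Topology/State pair to :func:`make_system` hands exclusive control
of the underlying storage to the System; the caller must not keep writing
through its own references afterwards.  This is a documented contract — it
cannot be enforced in Python — and violating it is undefined behavior of the
library.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .box import PeriodicBox
from .elements import guess_element, mass_of
from .errors import AccessKindError, EmptySelectionError, MolkitError

__all__ = ["Atom", "Topology", "State", "AccessKind", "System", "make_system"]


@dataclass
class Atom:
    """Time-independent identity of one atom."""

    name: str = "X"
    resname: str = "X"
    resid: int = 1
    chain: str = "A"
    mass: float = 0.0
    charge: float = 0.0
    element: str = ""
    type_name: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.name = self.name.strip() or "X"
        self.resname = self.resname.strip() or "X"
        self.chain = (self.chain.strip() or "A")[:1]
        if not self.element:
            self.element = guess_element(self.name)
        if self.mass < 0:
            raise ValueError(f"negative mass for atom {self.name!r}")

    @classmethod
    def with_mass(cls, **kw) -> "Atom":
        """Construct an Atom, filling mass from the element table if absent."""
        atom = cls(**kw)
        if atom.mass == 0.0 and "mass" not in kw:
            atom.mass = mass_of(atom.element)
        return atom


class Topology:
    """Ordered atom identities plus optional bonds.

    ``generation`` counts structural edits that can invalidate existing atom
    indices (deletions); appends do not bump it because they preserve all
    existing indices.
    """

    def __init__(self, atoms: Sequence[Atom] | None = None,
                 bonds: Iterable[tuple[int, int]] | None = None) -> None:
        self.atoms: list[Atom] = list(atoms or [])
        self.bonds: list[tuple[int, int]] = []
        self.generation: int = 0
        self._version: int = 0
        self._cache: dict[str, np.ndarray] = {}
        self._cache_version: int = -1
        if bonds:
            for i, j in bonds:
                self.add_bond(i, j)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def add_bond(self, i: int, j: int) -> None:
        n = len(self.atoms)
        if not (0 <= i < n and 0 <= j < n):
            raise MolkitError(f"bond ({i}, {j}) out of range for {n} atoms")
        if i == j:
            raise MolkitError(f"self-bond on atom {i}")
        self.bonds.append((min(i, j), max(i, j)))

    # -- cached column arrays used by the selection evaluator ---------
    def _columns(self) -> dict[str, np.ndarray]:
        if self._cache_version != self._version:
            self._cache = {
                "name": np.array([a.name for a in self.atoms], dtype=object),
                "resname": np.array([a.resname for a in self.atoms], dtype=object),
                "resid": np.array([a.resid for a in self.atoms], dtype=np.int64),
                "chain": np.array([a.chain for a in self.atoms], dtype=object),
                "mass": np.array([a.mass for a in self.atoms], dtype=float),
            }
            self._cache_version = self._version
        return self._cache

    @property
    def masses(self) -> np.ndarray:
        return self._columns()["mass"]

    def _structural_edit(self, bump_generation: bool) -> None:
        self._version += 1
        if bump_generation:
            self.generation += 1


class State:
    """One trajectory frame: coordinates (nm), optional box, time (ps)."""

    def __init__(self, coords: np.ndarray, box: Optional[PeriodicBox] = None,
                 time: float = 0.0, step: int = 0,
                 velocities: Optional[np.ndarray] = None,
                 forces: Optional[np.ndarray] = None) -> None:
        coords = np.ascontiguousarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an N x 3 array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords contain non-finite values")
        self.coords = coords
        self.box = box
        self.time = float(time)
        self.step = int(step)
        self.velocities = None if velocities is None else np.asarray(velocities, float)
        self.forces = None if forces is None else np.asarray(forces, float)
        self.generation: int = 0

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


class AccessKind(enum.Enum):
    """Selection access contracts; see the module docstring table."""

    MutableSerial = ("rw", True, False)
    BuilderSerial = ("rw", True, True)
    ImmutableParallel = ("ro", True, False)
    MutableParallel = ("rw", False, False)

    @property
    def writable(self) -> bool:
        return self.value[0] == "rw"

    @property
    def overlap_allowed(self) -> bool:
        return self.value[1]

    @property
    def needs_validity_check(self) -> bool:
        return self.value[2]

    @property
    def parallel(self) -> bool:
        return self in (AccessKind.ImmutableParallel, AccessKind.MutableParallel)


class System:
    """A Topology + State pair with a fixed access kind.

    Create with :func:`make_system`.  All selections are created through
    :meth:`select` / :meth:`select_all` / :meth:`select_indices` and carry
    the System's kind.
    """

    def __init__(self, topology: Topology, state: State, kind: AccessKind) -> None:
        from .selections import UsedIndexRegistry  # local: avoid cycle

        if topology.n_atoms != state.n_atoms:
            raise MolkitError(
                f"size mismatch: topology has {topology.n_atoms} atoms, "
                f"state has {state.n_atoms} coordinate rows")
        self.topology = topology
        self.state = state
        self.kind = kind
        self.registry = UsedIndexRegistry() if kind == AccessKind.MutableParallel else None

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    @property
    def generation(self) -> int:
        return self.topology.generation

    # -- selection creation -------------------------------------------
    def select(self, expr: str, *, within_self: bool = True):
        from .selections import select
        return select(self, expr, within_self=within_self)

    def try_select(self, expr: str, *, within_self: bool = True):
        from .selections import select
        try:
            return select(self, expr, within_self=within_self)
        except EmptySelectionError:
            return None

    def select_all(self):
        from .selections import select_indices
        return select_indices(self, np.arange(self.n_atoms))

    def select_indices(self, indices):
        from .selections import select_indices
        return select_indices(self, indices)

    # -- structural edits (BuilderSerial only) -------------------------
    def add_atoms(self, atoms: Sequence[Atom], coords: np.ndarray) -> None:
        """Append atoms; existing indices stay valid (generation unchanged)."""
        self._require_builder()
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        if len(atoms) == 0 and coords.size == 0:
            return
        if coords.shape != (len(atoms), 3):
            raise MolkitError("atoms and coords lengths differ")
        self.topology.atoms.extend(atoms)
        self.state.coords = np.vstack([self.state.coords, coords])
        self.topology._structural_edit(bump_generation=False)

    def delete_atoms(self, indices) -> None:
        """Delete atoms; remaining atoms are re-indexed compactly and every
        pre-existing selection becomes stale (generation is bumped)."""
        self._require_builder()
        idx = np.unique(np.asarray(indices, dtype=np.int64))
        if idx.size == 0:
            return
        if idx[0] < 0 or idx[-1] >= self.n_atoms:
            raise MolkitError(f"delete index out of range (n={self.n_atoms})")
        keep = np.ones(self.n_atoms, dtype=bool)
        keep[idx] = False
        remap = np.full(self.n_atoms, -1, dtype=np.int64)
        remap[keep] = np.arange(int(keep.sum()))
        self.topology.atoms = [a for a, k in zip(self.topology.atoms, keep) if k]
        self.topology.bonds = [
            (int(remap[i]), int(remap[j]))
            for i, j in self.topology.bonds if keep[i] and keep[j]
        ]
        self.state.coords = self.state.coords[keep]
        if self.state.velocities is not None:
            self.state.velocities = self.state.velocities[keep]
        if self.state.forces is not None:
            self.state.forces = self.state.forces[keep]
        self.topology._structural_edit(bump_generation=True)
        self.state.generation += 1

    def _require_builder(self) -> None:
        if self.kind != AccessKind.BuilderSerial:
            raise AccessKindError("structural edits require BuilderSerial")

    # -- frame loading (used by the parallel driver / CLI) -------------
    def load_state(self, state: State) -> None:
        """Replace the frame in place; atom count must be unchanged."""
        if state.n_atoms != self.n_atoms:
            raise MolkitError("frame atom count does not match the system")
        self.state.coords[:] = state.coords
        self.state.box = state.box
        self.state.time = state.time
        self.state.step = state.step

    def __repr__(self) -> str:
        return f"System({self.n_atoms} atoms, kind={self.kind.name})"


def make_system(topology: Topology, state: State, kind: AccessKind) -> System:
    """Bind a Topology and State into a System of the given access kind.

    The System takes exclusive control of the storage (documented contract;
    see the module docstring).  Raises on atom-count mismatch.
    """
    return System(topology, state, kind)
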