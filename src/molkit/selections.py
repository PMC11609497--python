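"""Kind-tagged selections, the used-index registry, and sub-selections.

A :class:`Selection` is a view over a subset of atoms of a :class:`System`.
It never copies atom data; all reads and writes go through the shared
Topology/State storage.  Its behavior is fixed by the System's access kind:

* serial kinds (MutableSerial, BuilderSerial) may overlap freely but must
  stay on the worker that created them;
* ImmutableParallel selections may overlap and cross workers but are
  read-only;
* MutableParallel selections are writable and cross workers, and are kept
  pairwise disjoint by the system's :class:`UsedIndexRegistry` — atom
  indices are claimed atomically at creation and released when the
  selection is dropped.

Three ways of deriving sub-selections mirror the narrowing techniques of
the design: ``subselect`` (parent kept alive, one child, all kinds except
MutableParallel), ``split_fragments`` (parent kept alive, a partition, all
kinds except MutableParallel) and ``into_fragments`` (parent consumed, a
partition, all kinds — the only one MutableParallel supports, because
consuming the parent is what guarantees parent and children never coexist).
"""

from __future__ import annotations

import threading
from typing import Callable, Iterable, Sequence

import numpy as np

from .core import AccessKind, Atom, System
from .errors import (AccessKindError, ConsumedSelectionError, EmptySelectionError,
                     OverlapError, RegistryError, StaleSelectionError)
from .grammar import EvalContext, parse

__all__ = [
    "IndexSet", "Selection", "UsedIndexRegistry", "select", "select_indices",
    "as_index_set", "by_residue", "by_chain", "validate_access",
]

IndexSet = np.ndarray  # sorted, unique, non-negative int64 indices


def as_index_set(indices, n_atoms: int | None = None) -> IndexSet:
    """Normalize to a sorted unique int64 array, bounds-checked if n given."""
    idx = np.unique(np.asarray(indices, dtype=np.int64))
    if idx.size and idx[0] < 0:
        raise ValueError("negative atom index")
    if n_atoms is not None and idx.size and idx[-1] >= n_atoms:
        raise ValueError(f"atom index {int(idx[-1])} out of range (n={n_atoms})")
    return idx


class UsedIndexRegistry:
    """Atom indices currently claimed by live MutableParallel selections.

    ``claim`` performs the disjointness test and the union atomically under
    one lock, so concurrent claims from parallel workers can never both
    succeed on intersecting sets.
    """

    def __init__(self) -> None:
        self._used: set[int] = set()
        self._lock = threading.Lock()

    @property
    def used(self) -> set[int]:
        with self._lock:
            return set(self._used)

    def claim(self, indices: Iterable[int]) -> None:
        s = set(int(i) for i in indices)
        with self._lock:
            clash = s & self._used
            if clash:
                raise OverlapError(
                    f"overlapping parallel selection (index {min(clash)} already in use)")
            self._used |= s

    def release(self, indices: Iterable[int]) -> None:
        s = set(int(i) for i in indices)
        with self._lock:
            if not s <= self._used:
                missing = min(s - self._used)
                raise RegistryError(
                    f"release of unclaimed index {missing}: registry out of sync")
            self._used -= s

    def replace(self, parent: Iterable[int], fragments: Sequence[Iterable[int]]) -> None:
        """Swap a parent claim for per-fragment claims in one indivisible step.

        The fragments must partition the parent set, so the union of claimed
        indices is unchanged and no third party can sneak a claim in between.
        """
        p = set(int(i) for i in parent)
        frag_sets = [set(int(i) for i in f) for f in fragments]
        union: set[int] = set()
        for f in frag_sets:
            if union & f:
                raise RegistryError("fragments overlap")
            union |= f
        if union != p:
            raise RegistryError("fragments do not partition the parent claim")
        with self._lock:
            if not p <= self._used:
                raise RegistryError("parent claim missing from registry")
            # partition: the used set is unchanged; only bookkeeping moves


class Selection:
    """A live view over ``index_set`` atoms of one System.

    Constructed via :func:`select` / :func:`select_indices` or the
    sub-selection methods; never directly.
    """

    def __init__(self, system: System, indices: IndexSet, *, _claim: bool = True):
        self._system = system
        self._indices = as_index_set(indices, system.n_atoms)
        if self._indices.size == 0:
            raise EmptySelectionError("empty selection")
        self.kind = system.kind
        self.birth_generation = system.generation
        self._alive = True
        self._registered = False
        if system.kind == AccessKind.MutableParallel and _claim:
            system.registry.claim(self._indices)
            self._registered = True
        elif system.kind == AccessKind.MutableParallel:
            self._registered = True  # claim transferred by into_fragments

    # -- lifecycle -----------------------------------------------------
    @property
    def alive(self) -> bool:
        return self._alive

    def release(self) -> None:
        """Drop the selection; for MutableParallel, release its registry claim."""
        if self._alive and self._registered:
            self._system.registry.release(self._indices)
            self._registered = False
        self._alive = False

    def __enter__(self) -> "Selection":
        return self

    def __exit__(self, *exc) -> None:
        self.release()

    def __del__(self):
        try:
            self.release()
        except Exception:
            pass

    def _check(self, write: bool = False) -> None:
        if not self._alive:
            raise ConsumedSelectionError("selection consumed")
        if self.kind.needs_validity_check and \
                self.birth_generation != self._system.generation:
            raise StaleSelectionError("selection invalidated by structural edit")
        if write and not self.kind.writable:
            raise AccessKindError("selection kind is read-only")

    # -- accessors ------------------------------------------------------
    @property
    def system(self) -> System:
        return self._system

    @property
    def index_set(self) -> IndexSet:
        self._check()
        return self._indices.copy()

    @property
    def n_atoms(self) -> int:
        self._check()
        return int(self._indices.size)

    def __len__(self) -> int:
        return self.n_atoms

    @property
    def coords(self) -> np.ndarray:
        """Copy of the selected coordinates (nm)."""
        self._check()
        return self._system.state.coords[self._indices].copy()

    def set_coords(self, coords: np.ndarray) -> None:
        self._check(write=True)
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self._indices.size, 3):
            raise ValueError("coordinate array shape mismatch")
        self._system.state.coords[self._indices] = coords

    @property
    def masses(self) -> np.ndarray:
        self._check()
        return self._system.topology.masses[self._indices]

    def atoms(self) -> list[Atom]:
        self._check()
        top = self._system.topology.atoms
        return [top[i] for i in self._indices]

    @property
    def box(self):
        self._check()
        return self._system.state.box

    # -- sub-selections --------------------------------------------------
    def subselect(self, expr: str) -> "Selection":
        """Narrow with an expression; parent stays alive.  Not MutableParallel."""
        self._check()
        self._forbid_parallel_mutable("subselect")
        node = parse(expr)
        ctx = EvalContext(self._system.topology, self._system.state)
        mask = node.evaluate(ctx, self._indices)
        sub = self._indices[mask]
        if sub.size == 0:
            raise EmptySelectionError(f"empty selection: {expr!r} within parent")
        return Selection(self._system, sub)

    def subselect_indices(self, local_indices) -> "Selection":
        """Narrow by positions *within* this selection; parent stays alive."""
        self._check()
        self._forbid_parallel_mutable("subselect")
        loc = as_index_set(local_indices, self._indices.size)
        return Selection(self._system, self._indices[loc])

    def split_fragments(self, key: Callable[[int], object]) -> list["Selection"]:
        """Partition by ``key(atom_index)``; parent stays alive.  Not MutableParallel."""
        self._check()
        self._forbid_parallel_mutable("split_fragments")
        return [Selection(self._system, part) for part in self._partition(key)]

    def into_fragments(self, key: Callable[[int], object]) -> list["Selection"]:
        """Partition by key, consuming the parent (all kinds).

        For MutableParallel the parent's registry claim becomes the
        fragments' claims in one indivisible registry operation, so at no
        point could a third party claim any of those indices.
        """
        self._check()
        parts = self._partition(key)
        if self.kind == AccessKind.MutableParallel:
            self._system.registry.replace(self._indices, parts)
            self._registered = False  # claim now owned by the fragments
            self._alive = False
            frags = [Selection(self._system, p, _claim=False) for p in parts]
        else:
            self._alive = False
            frags = [Selection(self._system, p) for p in parts]
        return frags

    def _partition(self, key: Callable[[int], object]) -> list[IndexSet]:
        groups: dict[object, list[int]] = {}
        for i in self._indices:
            groups.setdefault(key(int(i)), []).append(int(i))
        return [np.array(g, dtype=np.int64) for g in groups.values()]

    def _forbid_parallel_mutable(self, what: str) -> None:
        if self.kind == AccessKind.MutableParallel:
            raise AccessKindError(
                f"{what} is not implemented for MutableParallel selections; "
                "use into_fragments")

    def __repr__(self) -> str:
        state = "live" if self._alive else "consumed"
        return (f"Selection({self._indices.size} atoms, kind={self.kind.name}, "
                f"{state})")


def validate_access(sel: Selection) -> None:
    """Raise if the selection may no longer touch its atoms.

    Stale BuilderSerial selections (a structural edit happened after their
    creation) and consumed selections fail; every other kind passes with no
    work, matching the zero-cost contract of kinds that cannot go stale.
    """
    sel._check()


def select(system: System, expr: str, *, within_self: bool = True) -> Selection:
    """Evaluate a selection expression against the system's current state.

    Raises :class:`ParseError` on bad syntax, :class:`EmptySelectionError`
    when nothing matches, and :class:`OverlapError` when a MutableParallel
    claim would overlap a live selection.
    """
    if system.n_atoms == 0:
        raise EmptySelectionError("cannot select on an empty system")
    node = parse(expr)
    ctx = EvalContext(system.topology, system.state, include_self=within_self)
    cand = np.arange(system.n_atoms)
    mask = node.evaluate(ctx, cand)
    idx = cand[mask]
    if idx.size == 0:
        raise EmptySelectionError(f"empty selection: {expr!r}")
    return Selection(system, idx)


def select_indices(system: System, indices) -> Selection:
    """Create a selection from explicit 0-based atom indices."""
    return Selection(system, as_index_set(indices, system.n_atoms))


def by_residue(system: System) -> Callable[[int], object]:
    """Key function grouping atoms by (chain, resid)."""
    atoms = system.topology.atoms
    return lambda i: (atoms[i].chain, atoms[i].resid)


def by_chain(system: System) -> Callable[[int], object]:
    """Key function grouping atoms by chain letter."""
    atoms = system.topology.atoms
    return lambda i: atoms[i].chain
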