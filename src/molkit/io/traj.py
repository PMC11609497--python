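"""Uniform structure and trajectory entry points.

``read_structure``/``write_structure`` dispatch on extension (.pdb/.xyz,
optionally .gz).  ``open_trajectory`` returns an object satisfying the
TrajectoryReader contract: ``n_frames``, ``n_atoms``, and random-access
``read_frame(i)`` whose result is independent of prior reads, with
coordinates in nm.

Additional trajectory backends (e.g. an XTC codec) can be plugged in with
:func:`register_reader` without touching this module — the adapter only has
to honor the same contract.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable

import numpy as np

from ..core import State, Topology
from ..errors import FormatError
from .dcd import DCDReader, DCDWriter
from .pdb import iter_pdb_models, read_pdb, write_pdb
from .xyz import XYZTrajectoryReader, XYZTrajectoryWriter, read_xyz

__all__ = [
    "read_structure", "write_structure", "open_trajectory",
    "open_trajectory_writer", "register_reader", "PDBTrajectoryReader",
]

_READER_PLUGINS: dict[str, Callable[[str], object]] = {}


def register_reader(extension: str, factory: Callable[[str], object]) -> None:
    """Register a trajectory-reader factory for a file extension (e.g. '.xtc')."""
    _READER_PLUGINS[extension.lower().lstrip(".")] = factory


def _ext(path) -> str:
    name = str(path).lower()
    if name.endswith(".gz"):
        name = name[:-3]
    return Path(name).suffix.lstrip(".")


def read_structure(path) -> tuple[Topology, State]:
    """Read a PDB or XYZ structure (first model/frame only)."""
    ext = _ext(path)
    if ext == "pdb":
        return read_pdb(path)
    if ext == "xyz":
        return read_xyz(path)
    raise FormatError(f"unsupported structure format: .{ext}")


def write_structure(path, sel) -> None:
    """Write the selected atoms as a structure file (PDB or XYZ)."""
    ext = _ext(path)
    system = sel.system
    if ext == "pdb":
        write_pdb(path, system.topology, system.state.coords,
                  box=system.state.box, indices=sel.index_set)
    elif ext == "xyz":
        from .xyz import write_xyz
        symbols = [a.element or a.name for a in sel.atoms()]
        write_xyz(path, symbols, sel.coords)
    else:
        raise FormatError(f"unsupported structure format: .{ext}")


class PDBTrajectoryReader:
    """Multi-model PDB exposed through the TrajectoryReader contract."""

    def __init__(self, path) -> None:
        self.path = path
        topology, state = read_pdb(path)
        self._box = state.box
        self._frames = list(iter_pdb_models(path))
        if not self._frames:
            self._frames = [state.coords]
        self.n_atoms = topology.n_atoms
        self.dt = 1.0
        self.current = 0

    @property
    def n_frames(self) -> int:
        return len(self._frames)

    def read_frame(self, i: int) -> State:
        if not 0 <= i < self.n_frames:
            raise IndexError(f"frame {i} out of range (n_frames={self.n_frames})")
        self.current = i
        return State(np.array(self._frames[i]), box=self._box,
                     time=i * self.dt, step=i)

    def close(self) -> None:
        pass

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def open_trajectory(path):
    """Open a trajectory for random-access reading (.dcd, .xyz, multi-model .pdb)."""
    ext = _ext(path)
    if ext in _READER_PLUGINS:
        return _READER_PLUGINS[ext](path)
    if ext == "dcd":
        return DCDReader(path)
    if ext == "xyz":
        return XYZTrajectoryReader(path)
    if ext == "pdb":
        return PDBTrajectoryReader(path)
    raise FormatError(f"unsupported trajectory format: .{ext}")


def open_trajectory_writer(path, topology: Topology, indices=None, dt: float = 1.0,
                           with_unitcell: bool = True):
    """Open a trajectory writer (.dcd or .xyz) for the given atoms."""
    ext = _ext(path)
    idx = np.arange(topology.n_atoms) if indices is None else np.asarray(indices)
    if ext == "dcd":
        return DCDWriter(path, n_atoms=len(idx), dt=dt, with_unitcell=with_unitcell)
    if ext == "xyz":
        symbols = [topology.atoms[i].element or topology.atoms[i].name for i in idx]
        return XYZTrajectoryWriter(path, symbols)
    raise FormatError(f"unsupported trajectory format: .{ext}")
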