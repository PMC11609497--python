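"""Plain and multi-frame XYZ files (Angstrom in file, nm in memory)."""

from __future__ import annotations

import gzip
from typing import IO

import numpy as np

from ..core import Atom, State, Topology
from ..elements import mass_of
from ..errors import FormatError

__all__ = ["read_xyz", "write_xyz", "XYZTrajectoryReader", "XYZTrajectoryWriter"]

A_TO_NM = 0.1


def _open_text(path, mode: str = "rt") -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _read_frame(fh, path, expect_n: int | None = None):
    header = fh.readline()
    if not header.strip():
        return None, None, None
    try:
        n = int(header)
    except ValueError as exc:
        raise FormatError(f"bad XYZ atom-count line in {path}: {header!r}") from exc
    if expect_n is not None and n != expect_n:
        raise FormatError(f"inconsistent atom count in {path}: {n} vs {expect_n}")
    comment = fh.readline()
    symbols = []
    coords = np.empty((n, 3))
    for i in range(n):
        parts = fh.readline().split()
        if len(parts) < 4:
            raise FormatError(f"truncated XYZ record in {path} (atom {i})")
        symbols.append(parts[0])
        try:
            coords[i] = [float(p) for p in parts[1:4]]
        except ValueError as exc:
            raise FormatError(f"non-numeric XYZ coordinate in {path} (atom {i})") from exc
    return symbols, coords * A_TO_NM, comment


def read_xyz(path) -> tuple[Topology, State]:
    """Read the first frame of an XYZ file."""
    with _open_text(path) as fh:
        out = _read_frame(fh, path)
        if out[0] is None:
            raise FormatError(f"empty XYZ file {path}")
        symbols, coords, _ = out
    atoms = [Atom(name=s, resname="MOL", resid=1, chain="A",
                  element=s, mass=mass_of(s)) for s in symbols]
    return Topology(atoms), State(coords)


def write_xyz(path, symbols, coords_nm: np.ndarray, comment: str = "molkit") -> None:
    with _open_text(path, "wt") as fh:
        _write_frame(fh, symbols, coords_nm, comment)


def _write_frame(fh, symbols, coords_nm, comment) -> None:
    fh.write(f"{len(symbols)}\n{comment}\n")
    for s, (x, y, z) in zip(symbols, np.asarray(coords_nm) / A_TO_NM):
        fh.write(f"{s:<4s} {x:12.5f} {y:12.5f} {z:12.5f}\n")


class XYZTrajectoryReader:
    """Random-access reader over a concatenated multi-frame XYZ file."""

    def __init__(self, path) -> None:
        self.path = path
        self._fh = _open_text(path)
        self._offsets: list[int] = []
        self._n_atoms: int | None = None
        self._index_frames()
        self.current = 0
        self.dt = 1.0  # ps between frames (XYZ stores no time)

    def _index_frames(self) -> None:
        self._fh.seek(0)
        while True:
            pos = self._fh.tell()
            header = self._fh.readline()
            if not header.strip():
                break
            try:
                n = int(header)
            except ValueError as exc:
                raise FormatError(f"bad XYZ frame header in {self.path}") from exc
            if self._n_atoms is None:
                self._n_atoms = n
            elif n != self._n_atoms:
                raise FormatError(f"inconsistent atom count in {self.path}")
            self._offsets.append(pos)
            for _ in range(n + 1):
                self._fh.readline()

    @property
    def n_frames(self) -> int:
        return len(self._offsets)

    @property
    def n_atoms(self) -> int:
        return self._n_atoms or 0

    def read_frame(self, i: int) -> State:
        if not 0 <= i < self.n_frames:
            raise IndexError(f"frame {i} out of range (n_frames={self.n_frames})")
        self._fh.seek(self._offsets[i])
        _, coords, _ = _read_frame(self._fh, self.path, expect_n=self._n_atoms)
        self.current = i
        return State(coords, time=i * self.dt, step=i)

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class XYZTrajectoryWriter:
    """Appends frames to a multi-frame XYZ file."""

    def __init__(self, path, symbols) -> None:
        self.path = path
        self.symbols = list(symbols)
        self._fh = _open_text(path, "wt")
        self.n_written = 0

    def write_frame(self, coords_nm: np.ndarray, box=None,
                    time: float | None = None) -> None:
        if len(coords_nm) != len(self.symbols):
            raise FormatError("frame atom count does not match the writer")
        comment = f"frame {self.n_written}" + ("" if time is None else f" t={time} ps")
        _write_frame(self._fh, self.symbols, coords_nm, comment)
        self.n_written += 1

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
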