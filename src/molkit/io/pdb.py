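"""Fixed-column PDB reading and writing (ATOM/HETATM/CRYST1/MODEL).

Coordinates are Angstrom in the file and nm in memory (divide by 10 on
read, multiply on write).  PDB serials are renumbered from 1 on write;
residue ids are preserved verbatim.  ``.gz`` paths are transparently
decompressed/compressed.
"""

from __future__ import annotations

import gzip
from typing import IO, Iterator

import numpy as np

from ..box import PeriodicBox
from ..core import Atom, State, Topology
from ..elements import guess_element, mass_of
from ..errors import FormatError

__all__ = ["read_pdb", "write_pdb", "iter_pdb_models"]

A_TO_NM = 0.1


def _open_text(path, mode: str = "rt") -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, tuple[float, float, float]]:
    try:
        name = line[12:16]
        resname = line[17:20]
        chain = line[21:22]
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed PDB ATOM record at line {lineno}: {exc}") from exc
    occupancy, bfactor = 1.0, 0.0
    try:
        if line[54:60].strip():
            occupancy = float(line[54:60])
        if line[60:66].strip():
            bfactor = float(line[60:66])
    except ValueError as exc:
        raise FormatError(f"malformed occupancy/bfactor at line {lineno}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = guess_element(name)
    atom = Atom(name=name, resname=resname, resid=resid, chain=chain,
                mass=mass_of(element), element=element,
                occupancy=occupancy, bfactor=bfactor)
    return atom, (x * A_TO_NM, y * A_TO_NM, z * A_TO_NM)


def _parse_cryst1(line: str, lineno: int) -> PeriodicBox | None:
    try:
        a = float(line[6:15]) * A_TO_NM
        b = float(line[15:24]) * A_TO_NM
        c = float(line[24:33]) * A_TO_NM
        alpha = float(line[33:40])
        beta = float(line[40:47])
        gamma = float(line[47:54])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed CRYST1 record at line {lineno}") from exc
    if min(a, b, c) <= 0:
        return None  # placeholder CRYST1 (e.g. 1 1 1) means "no box"
    return PeriodicBox.from_lengths_angles(a, b, c, alpha, beta, gamma)


def read_pdb(path) -> tuple[Topology, State]:
    """Read the first model of a PDB file into (Topology, State)."""
    atoms: list[Atom] = []
    coords: list[tuple[float, float, float]] = []
    box = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                atom, xyz = _parse_atom_line(line, lineno)
                atoms.append(atom)
                coords.append(xyz)
            elif rec == "CRYST1":
                box = _parse_cryst1(line, lineno)
            elif rec.startswith(("ENDMDL", "END ")) or line.strip() == "END":
                if atoms:
                    break
    if not atoms:
        raise FormatError(f"no ATOM/HETATM records found in {path}")
    return Topology(atoms), State(np.array(coords), box=box)


def iter_pdb_models(path) -> Iterator[np.ndarray]:
    """Yield per-model coordinate arrays (nm) from a multi-model PDB."""
    coords: list[tuple[float, float, float]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                _, xyz = _parse_atom_line(line, lineno)
                coords.append(xyz)
            elif rec.startswith("ENDMDL"):
                if coords:
                    yield np.array(coords)
                    coords = []
    if coords:
        yield np.array(coords)


_PDB_LINE = ("{rec:<6s}{serial:>5d} {name:<4s}{alt:1s}{resname:<3s} {chain:1s}"
             "{resid:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bf:6.2f}"
             "          {element:>2s}\n")


def _format_name(name: str) -> str:
    # PDB convention: names shorter than 4 chars start in column 14
    return name if len(name) >= 4 else f" {name:<3s}"


def write_pdb(path, topology: Topology, coords: np.ndarray,
              box: PeriodicBox | None = None, indices=None,
              models: list[np.ndarray] | None = None) -> None:
    """Write selected atoms (all by default) as a PDB file.

    ``models`` (optional) writes a multi-model trajectory instead of the
    single ``coords`` frame.
    """
    idx = np.arange(topology.n_atoms) if indices is None else np.asarray(indices)
    with _open_text(path, "wt") as fh:
        if box is not None:
            a, b, c, al, be, ga = box.to_lengths_angles()
            fh.write(f"CRYST1{a / A_TO_NM:9.3f}{b / A_TO_NM:9.3f}{c / A_TO_NM:9.3f}"
                     f"{al:7.2f}{be:7.2f}{ga:7.2f} P 1           1\n")
        frames = [coords] if models is None else models
        for m, frame in enumerate(frames, start=1):
            if models is not None:
                fh.write(f"MODEL     {m:>4d}\n")
            for serial, i in enumerate(idx, start=1):
                atom = topology.atoms[i]
                x, y, z = frame[i] / A_TO_NM
                fh.write(_PDB_LINE.format(
                    rec="ATOM", serial=serial % 100000,
                    name=_format_name(atom.name), alt=" ",
                    resname=atom.resname[:3], chain=atom.chain or "A",
                    resid=atom.resid % 10000, icode=" ", x=x, y=y, z=z,
                    occ=atom.occupancy, bf=atom.bfactor,
                    element=atom.element[:2]))
            if models is not None:
                fh.write("ENDMDL\n")
        fh.write("END\n")
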