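"""CHARMM-dialect DCD trajectory reader/writer.

Binary layout: Fortran-style records (4-byte length marker, payload, same
marker).  The 84-byte header record starts with the magic ``CORD`` followed
by 20 int32 control words; icntrl[0] is the frame count, icntrl[8] the
number of fixed atoms (must be 0 here), icntrl[9] the timestep (float32,
stored in ps by this writer), icntrl[10] the unit-cell flag and icntrl[19]
the CHARMM version stamp.  Each frame holds an optional unit-cell record of
six float64 (A, gamma, B, beta, alpha, C; angles in degrees — values inside
[-1, 1] on read are taken as cosines, a common older dialect) and one
float32 record per coordinate axis, in Angstrom.

Byte order is auto-detected from the leading record marker.  Because every
frame occupies the same number of bytes, ``read_frame(i)`` is a constant
-time seek — the random-access contract.
"""

from __future__ import annotations

import math
import os
import struct

import numpy as np

from ..box import PeriodicBox
from ..core import State
from ..errors import FormatError

__all__ = ["DCDReader", "DCDWriter"]

A_TO_NM = 0.1


class DCDReader:
    def __init__(self, path) -> None:
        self.path = path
        self._fh = open(path, "rb")
        self._parse_header()
        self.current = 0

    def _record(self, expect: int | None = None) -> bytes:
        raw = self._fh.read(4)
        if len(raw) < 4:
            raise FormatError(f"truncated DCD record marker in {self.path}")
        (length,) = struct.unpack(self._e + "i", raw)
        if expect is not None and length != expect:
            raise FormatError(f"unexpected DCD record length {length} in {self.path}")
        payload = self._fh.read(length)
        tail = self._fh.read(4)
        if len(payload) < length or len(tail) < 4 or \
                struct.unpack(self._e + "i", tail)[0] != length:
            raise FormatError(f"corrupt DCD record markers in {self.path}")
        return payload

    def _parse_header(self) -> None:
        lead = self._fh.read(4)
        if len(lead) < 4:
            raise FormatError(f"{self.path} is not a DCD file (too short)")
        for endian in ("<", ">"):
            if struct.unpack(endian + "i", lead)[0] == 84:
                self._e = endian
                break
        else:
            raise FormatError(f"{self.path}: bad leading record marker (not a DCD)")
        self._fh.seek(0)
        header = self._record(expect=84)
        if header[:4] != b"CORD":
            raise FormatError(f"{self.path}: missing CORD magic")
        icntrl = struct.unpack(self._e + "20i", header[4:])
        self._header_nset = icntrl[0]
        self.istart = icntrl[1]
        self.nsavc = icntrl[2] or 1
        if icntrl[8] != 0:
            raise FormatError("DCD files with fixed atoms are not supported")
        (self.dt,) = struct.unpack(self._e + "f", header[4 + 9 * 4: 4 + 10 * 4])
        self.has_unitcell = icntrl[10] != 0
        self._record()  # title block
        natom_payload = self._record(expect=4)
        (self.n_atoms,) = struct.unpack(self._e + "i", natom_payload)
        self._data_start = self._fh.tell()
        cell_bytes = (4 + 48 + 4) if self.has_unitcell else 0
        xyz_bytes = 3 * (4 + 4 * self.n_atoms + 4)
        self._frame_bytes = cell_bytes + xyz_bytes
        size = os.fstat(self._fh.fileno()).st_size
        counted = (size - self._data_start) // self._frame_bytes
        self.n_frames = int(self._header_nset or counted)
        if self.n_frames > counted:
            raise FormatError(f"{self.path}: header promises {self.n_frames} frames, "
                              f"file holds {counted}")

    def _read_unitcell(self) -> PeriodicBox | None:
        payload = self._record(expect=48)
        a, gamma, b, beta, alpha, c = struct.unpack(self._e + "6d", payload)
        if min(a, b, c) <= 0:
            return None
        angles = []
        for ang in (alpha, beta, gamma):
            if -1.0 <= ang <= 1.0:
                ang = math.degrees(math.acos(ang))
            elif ang == 0.0:
                ang = 90.0
            angles.append(ang)
        return PeriodicBox.from_lengths_angles(
            a * A_TO_NM, b * A_TO_NM, c * A_TO_NM, *angles)

    def read_frame(self, i: int) -> State:
        if not 0 <= i < self.n_frames:
            raise IndexError(f"frame {i} out of range (n_frames={self.n_frames})")
        self._fh.seek(self._data_start + i * self._frame_bytes)
        box = self._read_unitcell() if self.has_unitcell else None
        axes = []
        for _ in range(3):
            payload = self._record(expect=4 * self.n_atoms)
            axes.append(np.frombuffer(payload, dtype=self._e + "f4"))
        coords = np.column_stack(axes).astype(float) * A_TO_NM
        self.current = i
        time = i * self.dt if self.dt > 0 else float(i)
        return State(coords, box=box, time=time, step=self.istart + i * self.nsavc)

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class DCDWriter:
    """Writes CHARMM-dialect DCD; the frame count is patched on close."""

    def __init__(self, path, n_atoms: int, dt: float = 1.0,
                 with_unitcell: bool = True) -> None:
        self.path = path
        self.n_atoms = int(n_atoms)
        self.dt = float(dt)
        self.with_unitcell = with_unitcell
        self.n_written = 0
        self._fh = open(path, "wb")
        self._write_header()

    def _rec(self, payload: bytes) -> None:
        marker = struct.pack("<i", len(payload))
        self._fh.write(marker + payload + marker)

    def _write_header(self) -> None:
        icntrl = [0] * 20
        icntrl[0] = 0          # nset, patched on close
        icntrl[1] = 0          # istart
        icntrl[2] = 1          # nsavc
        icntrl[10] = 1 if self.with_unitcell else 0
        icntrl[19] = 24        # charmm version stamp
        head = b"CORD" + struct.pack("<9i", *icntrl[:9]) \
            + struct.pack("<f", self.dt) + struct.pack("<10i", *icntrl[10:])
        self._rec(head)
        title = b"Created by molkit".ljust(80)
        self._rec(struct.pack("<i", 1) + title)
        self._rec(struct.pack("<i", self.n_atoms))

    def write_frame(self, coords_nm: np.ndarray, box: PeriodicBox | None = None,
                    time: float | None = None) -> None:
        coords_nm = np.asarray(coords_nm, dtype=float)
        if coords_nm.shape != (self.n_atoms, 3):
            raise FormatError("frame atom count does not match the writer")
        if self.with_unitcell:
            if box is not None:
                a, b, c, al, be, ga = box.to_lengths_angles()
            else:
                a = b = c = 0.0
                al = be = ga = 90.0
            self._rec(struct.pack("<6d", a / A_TO_NM, ga, b / A_TO_NM,
                                  be, al, c / A_TO_NM))
        xyz = (coords_nm / A_TO_NM).astype("<f4")
        for axis in range(3):
            self._rec(xyz[:, axis].tobytes())
        self.n_written += 1

    def close(self) -> None:
        if not self._fh.closed:
            self._fh.seek(4 + 4)  # marker + 'CORD'
            self._fh.write(struct.pack("<i", self.n_written))
            self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
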