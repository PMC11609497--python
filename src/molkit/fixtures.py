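"""Deterministic synthetic systems and trajectories with known ground truth.

Every test and benchmark in this package runs on generated data: a
protein-like random-walk polymer (plausible atom/residue names, chains,
element-derived masses, a periodic box) plus trajectories whose motion is
known exactly.  "Protein-like" means realistic *field values*, not
realistic geometry — the analysis operations under test are indifferent to
geometric realism as long as particle density is molecular-like.

Motion modes:

* ``rigid``  — each frame is frame 0 under a known rotation + translation;
  the per-frame transforms are stored in a JSON manifest, so fitting
  algorithms can be checked against ground truth.
* ``brownian`` — per-atom cumulative Gaussian steps of width sigma (nm).
* ``mixed``  — rigid motion plus Gaussian noise.

Same seed and parameters always produce the same files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .box import PeriodicBox
from .core import Atom, State, Topology
from .elements import mass_of
from .errors import MolkitError
from .io.traj import open_trajectory_writer
from .measure import RigidTransform

__all__ = ["MotionSpec", "generate_system", "generate_trajectory",
           "load_manifest", "manifest_transform"]

_BACKBONE = ["N", "CA", "C", "O"]
_SIDECHAIN = ["CB", "CG", "CD", "CE", "NZ", "OG", "SD", "CZ"]
_RESNAMES = ["ALA", "GLY", "SER", "LEU", "LYS", "ASP", "PHE", "VAL", "THR", "GLU"]
_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

_STEP = 0.15       # nm between consecutive atoms of a chain
_MIN_DIST = 0.08   # nm hard-sphere tolerance against recent atoms
_MARGIN = 0.2      # nm kept clear of the box faces


@dataclass
class MotionSpec:
    """Parameters of the synthetic per-frame motion."""

    mode: str = "rigid"                  # rigid | brownian | mixed
    seed: int = 0
    rotation_per_frame: float = 2.0      # degrees about a fixed random axis
    translation_per_frame: float = 0.02  # nm along a fixed random direction
    sigma: float = 0.01                  # nm Gaussian step width (brownian/mixed)

    def __post_init__(self):
        if self.mode not in ("rigid", "brownian", "mixed"):
            raise MolkitError(f"unknown motion mode {self.mode!r}")


def _atom_names(atoms_per_res: int) -> list[str]:
    names = list(_BACKBONE[:atoms_per_res])
    k = 0
    while len(names) < atoms_per_res:
        names.append(_SIDECHAIN[k % len(_SIDECHAIN)] + ("" if k < len(_SIDECHAIN)
                                                        else str(k // len(_SIDECHAIN))))
        k += 1
    return names


def generate_system(n_chains: int = 1, res_per_chain: int = 5,
                    atoms_per_res: int = 4, box_edge: float = 5.0,
                    seed: int = 0) -> tuple[Topology, State]:
    """Random-walk polymer chains inside a cubic box.

    Returns exactly ``n_chains * res_per_chain * atoms_per_res`` atoms with
    residue ids 1..res_per_chain per chain, chain letters A, B, ..., names
    N/CA/C/O plus side-chain dummies, and element-derived masses.
    """
    if min(n_chains, res_per_chain, atoms_per_res) < 1:
        raise MolkitError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    names = _atom_names(atoms_per_res)
    lo, hi = _MARGIN, box_edge - _MARGIN
    if hi <= lo:
        raise MolkitError(f"box edge {box_edge} nm too small")
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    for ci in range(n_chains):
        chain = _CHAIN_IDS[ci % len(_CHAIN_IDS)]
        pos = rng.uniform(lo, hi, size=3)
        for ri in range(res_per_chain):
            resname = _RESNAMES[(ci + ri) % len(_RESNAMES)]
            for ai, name in enumerate(names):
                if atoms:  # step from the previous atom, self-avoiding-ish
                    pos = _next_position(rng, pos, coords, lo, hi)
                    bonds.append((len(atoms) - 1, len(atoms)))
                atoms.append(Atom(name=name, resname=resname, resid=ri + 1,
                                  chain=chain, element="",
                                  mass=0.0))
                atoms[-1].mass = mass_of(atoms[-1].element)
                coords.append(pos.copy())
    state = State(np.array(coords), box=PeriodicBox.cubic(box_edge))
    return Topology(atoms, bonds=bonds), state


def _next_position(rng, pos, coords, lo, hi, max_tries: int = 60) -> np.ndarray:
    recent = np.array(coords[-30:])
    for _ in range(max_tries):
        step = rng.normal(size=3)
        cand = pos + _STEP * step / np.linalg.norm(step)
        if np.any(cand < lo) or np.any(cand > hi):
            continue
        if np.min(np.linalg.norm(recent - cand, axis=1)) < _MIN_DIST:
            continue
        return cand
    raise MolkitError("box too small to place atoms at the hard-sphere tolerance")


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


def generate_trajectory(topology: Topology, state: State, n_frames: int,
                        motion: MotionSpec, out_path) -> dict:
    """Write a trajectory (.dcd or .xyz) plus a ground-truth JSON manifest.

    Frame 0 equals the input state.  For rigid/mixed modes the manifest
    records the exact per-frame rotation matrix and translation (about the
    initial centroid), so ``fit_transform(frame_i, frame_0)`` can be checked
    against it.  The manifest is written next to the trajectory as
    ``<out_path>.manifest.json`` and also returned.
    """
    if n_frames < 1:
        raise MolkitError("n_frames must be >= 1")
    rng = np.random.default_rng(motion.seed)
    coords0 = state.coords.copy()
    centroid = coords0.mean(axis=0)
    axis = rng.normal(size=3)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)

    manifest: dict = {
        "mode": motion.mode, "seed": motion.seed, "n_frames": n_frames,
        "n_atoms": topology.n_atoms, "dt_ps": 1.0, "transforms": [],
    }
    writer = open_trajectory_writer(out_path, topology, dt=1.0,
                                    with_unitcell=state.box is not None)
    noise = np.zeros_like(coords0)
    try:
        for i in range(n_frames):
            if motion.mode in ("rigid", "mixed"):
                R = _rotation_about(axis, motion.rotation_per_frame * i)
                t_vec = motion.translation_per_frame * i * direction
                # rotate about the initial centroid, then translate
                full_t = centroid - R @ centroid + t_vec
                frame = coords0 @ R.T + full_t
                manifest["transforms"].append(
                    {"rotation": R.tolist(), "translation": full_t.tolist()})
            else:
                frame = coords0
            if motion.mode in ("brownian", "mixed"):
                if i > 0 and motion.sigma > 0:
                    noise = noise + rng.normal(scale=motion.sigma,
                                               size=coords0.shape)
                frame = frame + noise
            writer.write_frame(frame, box=state.box, time=float(i))
    finally:
        writer.close()
    Path(str(out_path) + ".manifest.json").write_text(json.dumps(manifest))
    return manifest


def load_manifest(traj_path) -> dict:
    """Read the ground-truth manifest written next to a generated trajectory."""
    return json.loads(Path(str(traj_path) + ".manifest.json").read_text())


def manifest_transform(manifest: dict, frame: int) -> RigidTransform:
    """The exact transform that produced ``frame`` from frame 0."""
    entry = manifest["transforms"][frame]
    return RigidTransform(np.array(entry["rotation"]),
                          np.array(entry["translation"]))
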