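"""The three canonical trajectory-analysis tasks, as library functions.

1. ``task_rmsd``      — align every frame on a reference and report RMSD.
2. ``task_within_com``— per frame, select atoms within a cutoff of an inner
   selection and report their (PBC-aware) center of mass.
3. ``task_extract``   — write a trajectory restricted to one selection.

All three run frame-parallel through :mod:`molkit.parallel` and produce
worker-count-independent output: partial results are gathered in frame
order, and any floating reductions happen over that ordered list.  CSV
outputs carry a reproducibility comment header (package version, inputs,
parameters) and state units in the column names.
"""

from __future__ import annotations

import csv
import math
from typing import Optional

import numpy as np

from . import __version__
from .core import AccessKind
from .errors import MolkitError
from .io.traj import open_trajectory, open_trajectory_writer, read_structure
from .measure import center_of_mass, fit_transform, rmsd
from .neighbor import search_within
from .parallel import FrameTask, analyze_trajectory

__all__ = ["task_rmsd", "task_within_com", "task_extract"]


def _csv_header(fh, name: str, params: dict) -> None:
    fh.write(f"# molkit {__version__} :: {name}\n")
    for k, v in params.items():
        fh.write(f"# {k} = {v}\n")


def task_rmsd(traj_path, ref_path, fit_expr: str = "all",
              measure_expr: Optional[str] = None, out_csv=None,
              workers: int = 1, mass_weighted: bool = True) -> list[dict]:
    """Per-frame RMSD after a (mass-weighted) Kabsch fit on ``fit_expr``.

    The fit is computed on the fit selection, the returned transform is
    applied to the measure selection (default: same as fit), and RMSD is
    taken against the reference structure.  Returns a list of row dicts and
    optionally writes CSV columns ``frame,time_ps,rmsd_nm``.
    """
    measure_expr = measure_expr or fit_expr
    ref_top, ref_state = read_structure(ref_path)
    from .core import make_system
    ref_system = make_system(ref_top, ref_state, AccessKind.ImmutableParallel)
    ref_fit = ref_system.select(fit_expr)
    ref_meas = ref_fit if measure_expr == fit_expr else ref_system.select(measure_expr)
    ref_fit_xyz = ref_fit.coords
    ref_meas_xyz = ref_meas.coords

    def setup(system):
        fit_sel = system.select(fit_expr)
        meas_sel = fit_sel if measure_expr == fit_expr else system.select(measure_expr)
        if fit_sel.n_atoms != len(ref_fit_xyz) or meas_sel.n_atoms != len(ref_meas_xyz):
            raise MolkitError("selection size mismatch between frame and reference")
        return fit_sel, meas_sel

    def per_frame(ctx, i, system):
        fit_sel, meas_sel = ctx
        t = fit_transform(fit_sel, ref_fit_xyz, mass_weighted=mass_weighted)
        aligned = t.apply(meas_sel.coords)
        return {"frame": i, "time_ps": system.state.time,
                "rmsd_nm": rmsd(aligned, ref_meas_xyz)}

    reader = open_trajectory(traj_path)
    try:
        task = FrameTask(topology=ref_top, per_frame=per_frame, setup=setup,
                         kind=AccessKind.ImmutableParallel)
        rows = analyze_trajectory(reader, task, workers=workers)
    finally:
        reader.close()

    if out_csv is not None:
        with open(out_csv, "w", newline="") as fh:
            _csv_header(fh, "rmsd", {
                "trajectory": traj_path, "reference": ref_path,
                "fit_selection": fit_expr, "measure_selection": measure_expr,
                "mass_weighted": mass_weighted, "workers": workers})
            w = csv.DictWriter(fh, fieldnames=["frame", "time_ps", "rmsd_nm"])
            w.writeheader()
            for row in rows:
                w.writerow({**row, "rmsd_nm": f"{row['rmsd_nm']:.9f}",
                            "time_ps": f"{row['time_ps']:g}"})
    return rows


def task_within_com(traj_path, ref_path, inner_expr: str, cutoff: float = 1.0,
                    out_csv=None, workers: int = 1) -> list[dict]:
    """Per-frame center of mass of all atoms within ``cutoff`` nm of
    ``inner_expr`` atoms (minimum-image distances and a circular-mean COM
    when the frame has a box).

    A frame where the distance query comes back empty is recorded as an
    error row (NaN center) and the run continues.
    """
    ref_top, _ = read_structure(ref_path)
    masses = ref_top.masses

    def per_frame(ctx, i, system):
        inner = system.select(inner_expr)
        box = system.state.box
        hits = search_within(system.state.coords, inner.index_set, cutoff,
                             box=box, include_query=True)
        row = {"frame": i, "time_ps": system.state.time, "n_atoms": int(hits.size)}
        if hits.size == 0:
            row.update(x_nm=math.nan, y_nm=math.nan, z_nm=math.nan, error="empty")
            return row
        com = center_of_mass(system.state.coords[hits], pbc=box is not None,
                             box=box, masses=masses[hits])
        row.update(x_nm=float(com[0]), y_nm=float(com[1]), z_nm=float(com[2]),
                   error="")
        return row

    reader = open_trajectory(traj_path)
    try:
        task = FrameTask(topology=ref_top, per_frame=per_frame,
                         kind=AccessKind.ImmutableParallel)
        rows = analyze_trajectory(reader, task, workers=workers)
    finally:
        reader.close()

    if out_csv is not None:
        cols = ["frame", "time_ps", "x_nm", "y_nm", "z_nm", "n_atoms", "error"]
        with open(out_csv, "w", newline="") as fh:
            _csv_header(fh, "within-com", {
                "trajectory": traj_path, "reference": ref_path,
                "inner_selection": inner_expr, "cutoff_nm": cutoff,
                "workers": workers})
            w = csv.DictWriter(fh, fieldnames=cols)
            w.writeheader()
            for row in rows:
                out = dict(row)
                for k in ("x_nm", "y_nm", "z_nm"):
                    out[k] = f"{row[k]:.9f}" if not math.isnan(row[k]) else "nan"
                out["time_ps"] = f"{row['time_ps']:g}"
                w.writerow(out)
    return rows


def task_extract(traj_path, ref_path, expr: str, out_traj, workers: int = 1) -> int:
    """Write a trajectory containing only the atoms matched by ``expr``.

    The selection is evaluated once against the reference structure; every
    frame of the output holds exactly those atoms in their original
    relative order.  Frames are gathered (possibly in parallel) and written
    sequentially in frame order.  Returns the number of frames written.
    """
    ref_top, ref_state = read_structure(ref_path)
    from .core import make_system
    ref_system = make_system(ref_top, ref_state, AccessKind.ImmutableParallel)
    sel = ref_system.select(expr)
    indices = sel.index_set

    def per_frame(ctx, i, system):
        return system.state.coords[indices].copy(), system.state.box, system.state.time

    reader = open_trajectory(traj_path)
    try:
        task = FrameTask(topology=ref_top, per_frame=per_frame,
                         kind=AccessKind.ImmutableParallel)
        frames = analyze_trajectory(reader, task, workers=workers)
        dt = getattr(reader, "dt", 1.0)
        has_box = frames[0][1] is not None if frames else False
        writer = open_trajectory_writer(out_traj, ref_top, indices=indices,
                                        dt=dt, with_unitcell=has_box)
        try:
            for coords, box, time in frames:
                writer.write_frame(coords, box=box, time=time)
        finally:
            writer.close()
    finally:
        reader.close()
    return len(frames)
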