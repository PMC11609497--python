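"""Frame-parallel trajectory analysis honoring the selection-kind contracts.

Most trajectory analyses treat frames independently, so the natural
parallel axis is the frame index.  :func:`analyze_trajectory` runs a
:class:`FrameTask` over every frame of a trajectory with a pool of worker
threads; every worker gets its *own* trajectory reader, its own State
buffer and its own System replica (the Topology object is shared but
read-only by contract), so no two workers ever write one State.  Results
come back in frame order regardless of completion order, which makes an
n-worker run bit-for-bit comparable to the serial one.

Serial selection kinds are pinned to the worker that creates them; a task
declaring a serial kind is rejected up front when more than one worker is
requested.

:func:`process_fragments` is the second entry point: within-frame
parallelism over disjoint MutableParallel fragments of one selection on the
*same* State, made sound by the used-index registry.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Any, Callable, Optional

from .core import AccessKind, State, System, Topology, make_system
from .errors import AccessKindError, MolkitError
from .io.traj import open_trajectory
from .selections import Selection

__all__ = ["FrameTask", "FrameTaskError", "analyze_trajectory", "process_fragments"]


class FrameTaskError(MolkitError):
    """A per-frame callback raised; carries the offending frame index."""

    def __init__(self, frame: int, cause: BaseException):
        self.frame = frame
        super().__init__(f"per-frame task failed at frame {frame}: {cause!r}")


@dataclass
class FrameTask:
    """One trajectory-analysis job.

    ``setup(system)`` runs once per worker and returns an arbitrary context
    (typically selections created on that worker's System replica);
    ``per_frame(context, frame_index, system)`` runs once per frame with
    the frame already loaded into the system and returns a partial result.
    """

    topology: Topology
    per_frame: Callable[[Any, int, System], Any]
    setup: Optional[Callable[[System], Any]] = None
    kind: AccessKind = AccessKind.ImmutableParallel


def _make_replica(task: FrameTask, first: State) -> tuple[System, Any]:
    state = State(first.coords.copy(), box=first.box,
                  time=first.time, step=first.step)
    system = make_system(task.topology, state, task.kind)
    ctx = task.setup(system) if task.setup is not None else None
    return system, ctx


def analyze_trajectory(reader, task: FrameTask, workers: int = 1) -> list:
    """Run ``task`` over every frame; results are ordered by frame index."""
    if workers < 1:
        raise ValueError("workers must be >= 1")
    if workers > 1 and not task.kind.parallel:
        raise AccessKindError(
            f"kind {task.kind.name} not usable across workers; "
            "use ImmutableParallel or MutableParallel")
    n = reader.n_frames
    results: list = [None] * n
    if n == 0:
        return results

    if workers == 1:
        system, ctx = _make_replica(task, reader.read_frame(0))
        for i in range(n):
            system.load_state(reader.read_frame(i))
            try:
                results[i] = task.per_frame(ctx, i, system)
            except Exception as exc:
                raise FrameTaskError(i, exc) from exc
        return results

    def run_worker(worker_id: int) -> None:
        own_reader = open_trajectory(reader.path)
        try:
            frames = range(worker_id, n, workers)
            system, ctx = _make_replica(task, own_reader.read_frame(frames[0]))
            for i in frames:
                system.load_state(own_reader.read_frame(i))
                try:
                    results[i] = task.per_frame(ctx, i, system)
                except Exception as exc:
                    raise FrameTaskError(i, exc) from exc
        finally:
            own_reader.close()

    with ThreadPoolExecutor(max_workers=workers) as pool:
        futures = [pool.submit(run_worker, w) for w in range(min(workers, n))]
        for fut in futures:
            fut.result()  # re-raise the first worker failure
    return results


def process_fragments(sel: Selection, key: Callable[[int], object],
                      fn: Callable[[Selection], Any], workers: int = 1) -> list:
    """Fragment a selection and apply ``fn`` to each fragment, in parallel.

    The parent is consumed (``into_fragments``); with ``workers > 1`` the
    selection must be MutableParallel (or read-only ImmutableParallel) so
    that concurrent work on one shared State is sound.  Results follow the
    fragments' first-occurrence order.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    if workers > 1 and not sel.kind.parallel:
        raise AccessKindError(
            f"kind {sel.kind.name} not usable across workers")
    fragments = sel.into_fragments(key)
    if workers == 1:
        return [fn(f) for f in fragments]
    with ThreadPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(fn, fragments))
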