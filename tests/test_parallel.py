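import threading

import numpy as np
import pytest

from molkit import (AccessKind, AccessKindError, FrameTask, analyze_trajectory,
                    center_of_mass, make_system, open_trajectory,
                    process_fragments, by_residue)
from molkit.fixtures import MotionSpec, generate_system, generate_trajectory
from molkit.parallel import FrameTaskError


@pytest.fixture
def traj(tmp_path):
    top, state = generate_system(2, 6, 4, 6.0, seed=11)
    path = tmp_path / "t.dcd"
    generate_trajectory(top, state, 30, MotionSpec(mode="mixed", seed=2), path)
    return top, path


def com_task(top):
    def per_frame(ctx, i, system):
        return center_of_mass(system.state.coords, masses=top.masses)
    return FrameTask(topology=top, per_frame=per_frame,
                     kind=AccessKind.ImmutableParallel)


class TestAnalyzeTrajectory:
    def test_worker_counts_agree_elementwise(self, traj):
        top, path = traj
        reader = open_trajectory(path)
        serial = analyze_trajectory(reader, com_task(top), workers=1)
        for workers in (2, 4, 8):
            got = analyze_trajectory(reader, com_task(top), workers=workers)
            for a, b in zip(serial, got):
                assert np.array_equal(a, b)
        reader.close()

    def test_per_frame_called_exactly_once_per_frame(self, traj):
        top, path = traj
        seen = []
        lock = threading.Lock()

        def per_frame(ctx, i, system):
            with lock:
                seen.append(i)
            return i

        reader = open_trajectory(path)
        out = analyze_trajectory(
            reader, FrameTask(topology=top, per_frame=per_frame,
                              kind=AccessKind.ImmutableParallel), workers=4)
        reader.close()
        assert sorted(seen) == list(range(30))
        assert out == list(range(30))

    def test_serial_kind_rejected_for_multiworker(self, traj):
        top, path = traj
        reader = open_trajectory(path)
        task = FrameTask(topology=top, per_frame=lambda c, i, s: i,
                         kind=AccessKind.MutableSerial)
        with pytest.raises(AccessKindError, match="not usable across workers"):
            analyze_trajectory(reader, task, workers=4)
        # the same task is fine on a single worker
        assert analyze_trajectory(reader, task, workers=1) == list(range(30))
        reader.close()

    def test_setup_runs_per_worker_and_context_flows(self, traj):
        top, path = traj
        contexts = []
        lock = threading.Lock()

        def setup(system):
            sel = system.select("name CA")
            with lock:
                contexts.append(sel)
            return sel

        def per_frame(ctx, i, system):
            return float(center_of_mass(ctx)[0])

        reader = open_trajectory(path)
        out = analyze_trajectory(
            reader, FrameTask(topology=top, per_frame=per_frame, setup=setup,
                              kind=AccessKind.ImmutableParallel), workers=3)
        reader.close()
        assert len(out) == 30 and len(contexts) == 3

    def test_per_frame_exception_reports_frame(self, traj):
        top, path = traj

        def per_frame(ctx, i, system):
            if i == 17:
                raise RuntimeError("boom")
            return i

        reader = open_trajectory(path)
        task = FrameTask(topology=top, per_frame=per_frame,
                         kind=AccessKind.ImmutableParallel)
        with pytest.raises(FrameTaskError, match="frame 17"):
            analyze_trajectory(reader, task, workers=1)
        reader.close()

    def test_bad_worker_count(self, traj):
        top, path = traj
        reader = open_trajectory(path)
        with pytest.raises(ValueError):
            analyze_trajectory(reader, com_task(top), workers=0)
        reader.close()


class TestProcessFragments:
    def test_fragment_results_follow_first_occurrence_order(self):
        top, state = generate_system(1, 6, 4, 6.0, seed=1)
        s = make_system(top, state, AccessKind.MutableParallel)
        sel = s.select_all()
        out = process_fragments(sel, by_residue(s),
                                lambda f: int(f.index_set[0]), workers=1)
        assert out == [0, 4, 8, 12, 16, 20]

    def test_concurrent_fragment_writes_on_shared_state(self):
        """Disjoint MutableParallel fragments may write one State safely."""
        top, state = generate_system(1, 8, 4, 6.0, seed=2)
        s = make_system(top, state, AccessKind.MutableParallel)
        before = state.coords.copy()
        sel = s.select_all()

        def shift(frag):
            from molkit import translate
            resid = top.atoms[int(frag.index_set[0])].resid
            translate(frag, [0.001 * resid, 0, 0])
            return resid

        out = process_fragments(sel, by_residue(s), shift, workers=4)
        assert sorted(out) == list(range(1, 9))
        for i, atom in enumerate(top.atoms):
            assert np.allclose(state.coords[i] - before[i],
                               [0.001 * atom.resid, 0, 0], atol=1e-12)

    def test_serial_kind_rejected_for_multiworker(self):
        top, state = generate_system(1, 4, 4, 6.0, seed=3)
        s = make_system(top, state, AccessKind.MutableSerial)
        with pytest.raises(AccessKindError):
            process_fragments(s.select_all(), by_residue(s),
                              lambda f: None, workers=2)
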