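import threading

import numpy as np
import pytest
from hypothesis import given, strategies as st

from molkit import (AccessKind, AccessKindError, ConsumedSelectionError,
                    EmptySelectionError, OverlapError, RegistryError,
                    UsedIndexRegistry, by_residue, center_of_mass,
                    validate_access)
from molkit.selections import as_index_set


class TestSelectionCreation:
    def test_empty_match_is_an_error(self, system_factory):
        s = system_factory()
        with pytest.raises(EmptySelectionError):
            s.select("resid 99")

    def test_try_select_returns_none_for_probing(self, system_factory):
        s = system_factory()
        assert s.try_select("resid 99") is None
        assert s.try_select("resid 1") is not None

    def test_kind_is_inherited_from_system(self, system_factory):
        for kind in AccessKind:
            sel = system_factory(kind).select("index 0-3")
            assert sel.kind == kind

    def test_index_set_is_sorted_unique(self, system_factory):
        s = system_factory()
        sel = s.select_indices([5, 3, 3, 1])
        assert list(sel.index_set) == [1, 3, 5]


class TestMutableParallelOverlap:
    def test_overlapping_creation_rejected_disjoint_accepted(self, system_factory):
        s = system_factory(AccessKind.MutableParallel)
        first = s.select_indices([0, 1, 2])
        with pytest.raises(OverlapError):
            s.select_indices([2, 3])
        disjoint = s.select_indices([3, 4])
        assert s.registry.used == {0, 1, 2, 3, 4}
        first.release()
        disjoint.release()
        assert s.registry.used == set()

    def test_release_then_reclaim(self, system_factory):
        s = system_factory(AccessKind.MutableParallel)
        sel = s.select_indices([0, 1, 2])
        sel.release()
        assert s.select_indices([2, 3]).n_atoms == 2

    def test_serial_kinds_may_overlap(self, system_factory):
        s = system_factory(AccessKind.MutableSerial)
        a = s.select("index 0-5")
        b = s.select("index 3-8")
        assert a.n_atoms == 6 and b.n_atoms == 6


class TestRegistry:
    def test_claim_release_cycle(self):
        reg = UsedIndexRegistry()
        reg.claim([0, 1, 2])
        with pytest.raises(OverlapError, match="index 2"):
            reg.claim([2, 3])
        reg.release([0, 1, 2])
        reg.claim([2, 3])
        assert reg.used == {2, 3}

    def test_release_of_unclaimed_is_a_registry_error(self):
        reg = UsedIndexRegistry()
        reg.claim([0])
        with pytest.raises(RegistryError):
            reg.release([5])

    def test_release_empty_is_noop(self):
        reg = UsedIndexRegistry()
        reg.release([])
        assert reg.used == set()

    def test_shadow_model_over_random_operations(self, system_factory):
        """registry.used tracks the union of live selections exactly."""
        s = system_factory(AccessKind.MutableParallel,
                           res_per_chain=10, atoms_per_res=6)
        rng = np.random.default_rng(2024)
        n = s.n_atoms
        live = []           # selections
        shadow = set()      # expected union of live index sets
        for _ in range(10_000):
            op = rng.integers(0, 3)
            if op == 0:
                size = int(rng.integers(1, 6))
                want = rng.choice(n, size=size, replace=False)
                try:
                    sel = s.select_indices(want)
                    live.append(sel)
                    shadow |= set(int(i) for i in sel.index_set)
                except OverlapError:
                    assert set(int(i) for i in want) & shadow
            elif op == 1 and live:
                sel = live.pop(int(rng.integers(len(live))))
                shadow -= set(int(i) for i in sel.index_set)
                sel.release()
            elif op == 2 and live:
                k = int(rng.integers(len(live)))
                sel = live.pop(k)
                frags = sel.into_fragments(lambda i: i % 2)
                live.extend(frags)  # union unchanged
            assert s.registry.used == shadow
        assert s.registry.used == shadow

    def test_concurrent_claims_never_intersect(self):
        """4 workers hammer one registry; no two live claims may overlap."""
        reg = UsedIndexRegistry()
        mirror_lock = threading.Lock()
        mirror: set[int] = set()
        violations = []

        def worker(seed):
            rng = np.random.default_rng(seed)
            for _ in range(2500):
                want = set(int(i) for i in rng.integers(0, 40, size=3))
                try:
                    reg.claim(want)
                except OverlapError:
                    continue
                with mirror_lock:
                    if mirror & want:
                        violations.append(want)
                    mirror.update(want)
                with mirror_lock:
                    mirror.difference_update(want)
                reg.release(want)

        threads = [threading.Thread(target=worker, args=(s,)) for s in range(4)]
        for t in threads:
            t.start()
        for t in threads:
            t.join()
        assert violations == []
        assert reg.used == set()


class TestSubselect:
    def test_never_widens(self, system_factory):
        sel = system_factory().select("index 2-7")
        assert list(sel.subselect("index 0-100").index_set) == [2, 3, 4, 5, 6, 7]

    def test_narrows_to_residue(self, system_factory):
        s = system_factory()
        parent = s.select("resid 1-3")
        child = parent.subselect("resid 2")
        expect = [i for i, a in enumerate(s.topology.atoms) if a.resid == 2]
        assert list(child.index_set) == expect
        assert parent.alive  # parent kept alive

    def test_oracle_equivalence_with_system_wide_select(self, system_factory):
        s = system_factory()
        parent = s.select("index 3-14")
        for expr in ["name CA", "resid 2", "name C or name O",
                     "within 0.6 of (index 0)"]:
            wide = set(s.select(expr).index_set)
            expect = sorted(wide & set(parent.index_set))
            if expect:
                assert list(parent.subselect(expr).index_set) == expect
            else:
                with pytest.raises(EmptySelectionError):
                    parent.subselect(expr)

    def test_forbidden_for_mutable_parallel(self, system_factory):
        sel = system_factory(AccessKind.MutableParallel).select("all")
        with pytest.raises(AccessKindError, match="not implemented"):
            sel.subselect("resid 1")

    def test_empty_result_is_an_error(self, system_factory):
        sel = system_factory().select("resid 1")
        with pytest.raises(EmptySelectionError):
            sel.subselect("resid 3")


class TestSplitAndFragment:
    def test_split_partitions_and_keeps_parent(self, system_factory):
        s = system_factory()
        parent = s.select("all")
        frags = parent.split_fragments(by_residue(s))
        assert len(frags) == 3
        union = sorted(np.concatenate([f.index_set for f in frags]))
        assert union == list(parent.index_set)
        sizes = {f.n_atoms for f in frags}
        assert sizes == {7}
        assert center_of_mass(parent) is not None  # parent still usable

    def test_constant_key_gives_single_fragment(self, system_factory):
        parent = system_factory().select("index 0-5")
        frags = parent.split_fragments(lambda i: 0)
        assert len(frags) == 1
        assert list(frags[0].index_set) == list(parent.index_set)

    def test_into_fragments_consumes_parent(self, system_factory):
        parent = system_factory().select("index 0-5")
        frags = parent.into_fragments(lambda i: 0)
        assert len(frags) == 1 and not parent.alive
        with pytest.raises(ConsumedSelectionError):
            _ = parent.coords

    def test_into_fragments_mutable_parallel_preserves_registry(self, system_factory):
        s = system_factory(AccessKind.MutableParallel)
        parent = s.select("index 0-5")
        claimed_before = s.registry.used
        frags = parent.into_fragments(lambda i: s.topology.atoms[i].resid)
        assert s.registry.used == claimed_before  # no intermediate gap
        sets = [set(int(j) for j in f.index_set) for f in frags]
        for i, a in enumerate(sets):
            for b in sets[i + 1:]:
                assert not a & b
        for f in frags:
            f.release()
        assert s.registry.used == set()

    @given(st.integers(0, 10_000))
    def test_partition_property_random_parent_and_key(self, system_factory, seed):
        rng = np.random.default_rng(seed)
        s = system_factory()
        size = int(rng.integers(1, s.n_atoms))
        parent = s.select_indices(rng.choice(s.n_atoms, size, replace=False))
        mod = int(rng.integers(1, 6))
        frags = parent.split_fragments(lambda i: i % mod)
        all_idx = np.concatenate([f.index_set for f in frags])
        assert len(all_idx) == len(set(all_idx))  # pairwise disjoint
        assert sorted(all_idx) == list(parent.index_set)


class TestValidity:
    def test_builder_selection_goes_stale_after_delete(self, system_factory):
        s = system_factory(AccessKind.BuilderSerial)
        sel = s.select("index 0-4")
        validate_access(sel)  # fine before any edit
        s.delete_atoms([s.n_atoms - 1])
        from molkit import StaleSelectionError
        with pytest.raises(StaleSelectionError):
            validate_access(sel)

    def test_builder_selection_survives_append(self, system_factory):
        from molkit import Atom
        s = system_factory(AccessKind.BuilderSerial)
        sel = s.select("index 0-4")
        s.add_atoms([Atom(name="H")], np.zeros((1, 3)))
        validate_access(sel)
        assert sel.n_atoms == 5

    def test_serial_selection_unaffected_by_coordinate_writes(self, system_factory):
        s = system_factory(AccessKind.MutableSerial)
        sel = s.select("index 0-4")
        sel.set_coords(sel.coords + 1.0)
        validate_access(sel)

    def test_immutable_parallel_rejects_writes(self, system_factory):
        sel = system_factory(AccessKind.ImmutableParallel).select("all")
        with pytest.raises(AccessKindError, match="read-only"):
            sel.set_coords(sel.coords)

    def test_consumed_selection_every_accessor_raises(self, system_factory):
        sel = system_factory().select("index 0-3")
        sel.into_fragments(lambda i: i)
        for access in (lambda: sel.coords, lambda: sel.masses,
                       lambda: sel.index_set, lambda: sel.n_atoms,
                       lambda: sel.subselect("all")):
            with pytest.raises(ConsumedSelectionError):
                access()


class TestIndexSetHelper:
    def test_bounds_check(self):
        with pytest.raises(ValueError):
            as_index_set([0, 10], n_atoms=5)
        with pytest.raises(ValueError):
            as_index_set([-1])
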