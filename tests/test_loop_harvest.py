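"""Loop harvesting, screening thresholds, connectivity pruning, persistence."""

import numpy as np
import pytest

from petei.loop_harvest import (
    AttachmentSpec,
    GeometrySignature,
    LoopDatabase,
    LoopRecord,
    SIGNATURE_KEYS,
    build_database,
    combinatorial_diversity,
    harvest_loops,
    load_database,
    match_candidate,
    prune_by_connectivity,
    save_database,
    scaffold_signature,
    screen_loop_pair,
    screen_loop_vs_scaffold,
    signature_from_residues,
)
from petei.structure_model import Residue, StructureModel, make_atom

from conftest import random_rotation


def _flank_residue(res_name, seq, origin, chain="A"):
    origin = np.asarray(origin, float)
    atoms = [
        make_atom("N", "N", origin + [-1.2, 0.3, 0.0], res_name),
        make_atom("CA", "C", origin, res_name),
        make_atom("C", "C", origin + [1.25, 0.3, 0.0], res_name),
        make_atom("O", "O", origin + [1.25, 0.3, 1.23], res_name),
    ]
    res = Residue(res_name, seq, atoms, chain_id=chain)
    if res_name != "GLY":
        res.atoms.append(make_atom("CB", "C", origin + [0.0, -1.2, -0.95], res_name))
    return res


def _dummy_loop(loop_id, slot_id, atoms, res_name="GLY"):
    res = Residue(res_name, 1, list(atoms), chain_id="L")
    sig = GeometrySignature(tuple([5.0] * 7))
    return LoopRecord(loop_id=loop_id, slot_id=slot_id, sequence=res.one_letter,
                      residues=[res], signature=sig)


class TestSignatures:
    def test_constructed_ca_separation_is_reported_exactly(self):
        ri = _flank_residue("ALA", 1, [0, 0, 0])
        rf = _flank_residue("ALA", 2, [8.0, 0, 0])
        sig = signature_from_residues(ri, rf)
        assert sig.as_dict()["CAi_CAf"] == pytest.approx(8.0, abs=1e-12)

    def test_glycine_flank_uses_virtual_cb(self):
        ri = _flank_residue("GLY", 1, [0, 0, 0])
        rf = _flank_residue("ALA", 2, [7.0, 0, 0])
        sig = signature_from_residues(ri, rf)
        assert all(np.isfinite(d) and d > 0 for d in sig.distances)

    def test_signature_is_rotation_invariant(self, scaffold_and_specs):
        scaffold, specs = scaffold_and_specs
        sig = scaffold_signature(scaffold, specs[0])
        rng = np.random.default_rng(5)
        moved = scaffold.transform(random_rotation(rng), rng.uniform(-9, 9, 3))
        sig2 = scaffold_signature(moved, specs[0])
        np.testing.assert_allclose(sig2.distances, sig.distances, atol=1e-6)

    def test_missing_attachment_residue_is_an_error(self, scaffold_and_specs):
        scaffold, _ = scaffold_and_specs
        bad = AttachmentSpec(slot_id=9, chain_id="A", initial_residue=900,
                             final_residue=905, replaced_range=(901, 904))
        with pytest.raises(KeyError):
            scaffold_signature(scaffold, bad)


class TestMatchCandidate:
    def _sig(self, values):
        return GeometrySignature(tuple(values))

    def test_identical_signatures_match_with_zero_deviations(self):
        s = self._sig([6.0, 7.0, 6.5, 6.5, 6.0, 8.0, 6.0])
        ok, dev = match_candidate(s, s)
        assert ok and all(d == 0.0 for d in dev.values())

    def test_single_excess_deviation_rejects(self):
        s = self._sig([6.0, 7.0, 6.5, 6.5, 6.0, 8.0, 6.0])
        c = self._sig([6.0, 7.0, 6.5, 6.5, 6.0, 8.0, 6.30])
        ok, dev = match_candidate(c, s)
        assert not ok and dev["Ci_Cf"] == pytest.approx(0.30)

    def test_boundary_is_inclusive_at_the_tolerance(self):
        s = self._sig([6.0] * 7)
        at = self._sig([6.225] * 7)
        above = self._sig([6.226] * 7)
        assert match_candidate(at, s)[0]
        assert not match_candidate(above, s)[0]


class TestHarvest:
    def test_scaffold_recovers_its_own_native_loops(self, scaffold_and_specs):
        scaffold, specs = scaffold_and_specs
        found = harvest_loops([scaffold], scaffold, specs)
        for sp in specs:
            loops = found[sp.slot_id]
            assert len(loops) == 1
            lo, hi = sp.replaced_range
            assert loops[0].loop_id == f"{scaffold.id}/A/{lo}-{hi}"
            ok, dev = match_candidate(
                loops[0].signature, scaffold_signature(scaffold, sp)
            )
            assert ok and max(dev.values()) < 1e-9

    def test_planted_loops_recovered_exactly(self, scaffold_and_specs, corpus_and_labels):
        scaffold, specs = scaffold_and_specs
        corpus, labels = corpus_and_labels
        found = harvest_loops(corpus, scaffold, specs)
        recovered = {sid: {lp.loop_id for lp in loops} for sid, loops in found.items()}
        expected = {sp.slot_id: set() for sp in specs}
        for lab in labels:
            if lab["kind"] == "planted":
                expected[lab["slot_id"]].add(lab["expected_loop_id"])
        assert recovered == expected

    def test_empty_corpus_yields_empty_result(self, scaffold_and_specs):
        scaffold, specs = scaffold_and_specs
        found = harvest_loops([], scaffold, specs)
        assert all(not loops for loops in found.values())

    def test_harvest_invariant_under_corpus_rigid_motion(self, scaffold_and_specs, corpus_and_labels):
        scaffold, specs = scaffold_and_specs
        corpus, _ = corpus_and_labels
        entry = corpus[0]
        rng = np.random.default_rng(17)
        moved = entry.transform(random_rotation(rng), rng.uniform(-15, 15, 3))
        a = harvest_loops([entry], scaffold, specs)
        b = harvest_loops([moved], scaffold, specs)
        ids_a = {sid: [lp.loop_id for lp in v] for sid, v in a.items()}
        ids_b = {sid: [lp.loop_id for lp in v] for sid, v in b.items()}
        assert ids_a == ids_b
        # superposed coordinates agree as well
        for sid in ids_a:
            for la, lb in zip(a[sid], b[sid]):
                ca = np.array([at.coord for at in la.atoms()])
                cb = np.array([at.coord for at in lb.atoms()])
                np.testing.assert_allclose(ca, cb, atol=1e-6)


class TestScreens:
    def _scaffold_cloud(self, n=30):
        residues = [Residue("ALA", i + 1, [make_atom("CA", "C", [i * 4.0, 0, 0], "ALA")],
                            chain_id="A") for i in range(n)]
        return StructureModel(id="sc", chains={"A": residues})

    def test_distant_neutral_loop_passes(self):
        sc = self._scaffold_cloud()
        loop = _dummy_loop("far", 1, [make_atom("CA", "C", [0, 0, 100])])
        ok, clashes, energy = screen_loop_vs_scaffold(loop, sc)
        assert ok and clashes == 0 and energy == pytest.approx(0.0, abs=1e-6)

    def test_seventeen_overlaps_fail_regardless_of_energy(self):
        sc = self._scaffold_cloud()
        atoms = [make_atom(f"C{i}", "C", [i * 4.0, 0.5, 0]) for i in range(17)]
        loop = _dummy_loop("clashy", 1, atoms)
        ok, clashes, _ = screen_loop_vs_scaffold(loop, sc)
        assert clashes == 17 and not ok

    def test_sixteen_clashes_within_energy_budget_pass(self):
        sc = self._scaffold_cloud()
        # just inside the clash distance but far enough for modest LJ repulsion
        atoms = [make_atom(f"C{i}", "C", [i * 4.0, 3.35, 0]) for i in range(16)]
        loop = _dummy_loop("edgy", 1, atoms)
        ok, clashes, energy = screen_loop_vs_scaffold(loop, sc)
        assert clashes == 16 and energy <= 237.5 and ok

    def test_energy_threshold_fails_independently_of_clashes(self):
        sc = self._scaffold_cloud()
        loop = _dummy_loop("hot", 1, [make_atom("CA", "C", [0, 0, 50])])
        ok, clashes, energy = screen_loop_vs_scaffold(loop, sc, max_energy=-1.0)
        assert clashes == 0 and not ok

    def test_pair_screen_thresholds(self):
        mk = lambda xs, lid, sid: _dummy_loop(lid, sid, [make_atom(f"C{i}", "C", [x, 0, 0]) for i, x in enumerate(xs)])
        quiet_a = mk([0.0, 10.0], "a", 1)
        quiet_b = mk([100.0, 110.0], "b", 2)
        assert screen_loop_pair(quiet_a, quiet_b)[0]
        # 4 overlapping pairs -> fail on clashes
        over_a = mk([0.0, 10.0, 20.0, 30.0], "a", 1)
        over_b = mk([0.5, 10.5, 20.5, 30.5], "b", 2)
        ok, clashes, _ = screen_loop_pair(over_a, over_b)
        assert clashes == 4 and not ok
        # modest clashes but energy above threshold -> fail
        ok, clashes, energy = screen_loop_pair(quiet_a, quiet_b, max_energy=-1.0)
        assert not ok

    def test_same_slot_pair_is_an_error(self):
        a = _dummy_loop("a", 1, [make_atom("CA", "C", [0, 0, 0])])
        b = _dummy_loop("b", 1, [make_atom("CA", "C", [9, 0, 0])])
        with pytest.raises(ValueError):
            screen_loop_pair(a, b)


def _toy_db(slot_loops, compat):
    slots = {
        sid: [_dummy_loop(lid, sid, [make_atom("CA", "C", [i, 0, 0])])
              for i, lid in enumerate(loop_ids)]
        for sid, loop_ids in slot_loops.items()
    }
    return LoopDatabase(slots=slots, compatibility=set(compat))


class TestPruning:
    def test_fully_connected_db_is_a_fixed_point(self):
        db = _toy_db(
            {1: ["a1", "a2"], 2: ["b1", "b2"]},
            {("a1", "b1"), ("a1", "b2"), ("a2", "b1"), ("a2", "b2")},
        )
        pruned = prune_by_connectivity(db)
        assert {lp.loop_id for v in pruned.slots.values() for lp in v} == {"a1", "a2", "b1", "b2"}
        assert pruned.compatibility == db.compatibility

    def test_loop_without_partner_in_some_slot_is_removed(self):
        db = _toy_db(
            {1: ["a1", "a2"], 2: ["b1"], 3: ["c1"]},
            {("a1", "b1"), ("a1", "c1"), ("a2", "b1"), ("b1", "c1")},
        )
        pruned = prune_by_connectivity(db)  # a2 has no slot-3 partner
        assert {lp.loop_id for lp in pruned.slots[1]} == {"a1"}

    def test_cascading_removal_reaches_a_verified_fixed_point(self):
        # removing x (no slot-3 partner) leaves y partnerless in slot 1
        db = _toy_db(
            {1: ["a", "x"], 2: ["y", "b"], 3: ["c"]},
            {("a", "b"), ("a", "c"), ("x", "y"), ("b", "c")},
        )
        pruned = prune_by_connectivity(db)
        kept = {lp.loop_id for v in pruned.slots.values() for lp in v}
        assert kept == {"a", "b", "c"}
        # brute-force recheck of the connectivity condition on the result
        slot_of = {lp.loop_id: sid for sid, v in pruned.slots.items() for lp in v}
        for lid, sid in slot_of.items():
            for other in pruned.slots:
                if other == sid:
                    continue
                assert any(
                    pruned.are_compatible(lid, lp.loop_id)
                    for lp in pruned.slots[other]
                )

    def test_emptied_slot_is_an_error(self):
        db = _toy_db({1: ["a"], 2: ["b"]}, set())
        with pytest.raises(ValueError, match="no viable loops"):
            prune_by_connectivity(db)


class TestDiversity:
    def test_published_slot_counts_multiply_out(self):
        db = _toy_db({1: [f"a{i}" for i in range(707)],
                      2: [f"b{i}" for i in range(708)],
                      3: [f"c{i}" for i in range(958)]}, set())
        assert combinatorial_diversity(db) == 707 * 708 * 958 == 479_532_648

    def test_single_loops_give_unit_diversity(self):
        assert combinatorial_diversity(_toy_db({1: ["a"], 2: ["b"], 3: ["c"]}, set())) == 1

    def test_empty_slot_zeroes_the_product(self):
        assert combinatorial_diversity(_toy_db({1: ["a"], 2: []}, set())) == 0


class TestPersistence:
    @pytest.fixture()
    def small_db(self, scaffold_and_specs, corpus_and_labels):
        scaffold, specs = scaffold_and_specs
        corpus, _ = corpus_and_labels
        return build_database(corpus[:18], scaffold, specs[:1], prune=False)

    def test_save_load_round_trip_is_lossless(self, tmp_path, small_db):
        save_database(small_db, tmp_path)
        back = load_database(tmp_path)
        assert sorted(back.loop_ids()) == sorted(small_db.loop_ids())
        for lid in small_db.loop_ids():
            a, b = small_db.loop(lid), back.loop(lid)
            assert a.sequence == b.sequence
            assert a.scaffold_clashes == b.scaffold_clashes
            assert a.scaffold_energy == pytest.approx(b.scaffold_energy, abs=1e-5)
            ca = np.array([at.coord for at in a.atoms()])
            cb = np.array([at.coord for at in b.atoms()])
            np.testing.assert_allclose(ca, cb, atol=1e-3)
        assert back.compatibility == small_db.compatibility
        assert {k: len(v) for k, v in back.interaction_sites.items()} == {
            k: len(v) for k, v in small_db.interaction_sites.items()
        }

    def test_on_disk_loop_count_matches_memory(self, tmp_path, small_db):
        save_database(small_db, tmp_path)
        assert len(list((tmp_path / "loops").glob("*.pdb"))) == small_db.n_loops()

    def test_truncated_compatibility_file_is_an_error(self, tmp_path, small_db):
        save_database(small_db, tmp_path)
        manifest = (tmp_path / "manifest.yaml").read_text()
        import yaml as _yaml

        data = _yaml.safe_load(manifest)
        data["n_compatibility"] = data["n_compatibility"] + 1
        (tmp_path / "manifest.yaml").write_text(_yaml.safe_dump(data))
        with pytest.raises(ValueError, match="truncated|corrupt"):
            load_database(tmp_path)

    def test_version_mismatch_is_an_error(self, tmp_path, small_db):
        save_database(small_db, tmp_path)
        import yaml as _yaml

        data = _yaml.safe_load((tmp_path / "manifest.yaml").read_text())
        data["format_version"] = 999
        (tmp_path / "manifest.yaml").write_text(_yaml.safe_dump(data))
        with pytest.raises(ValueError, match="version"):
            load_database(tmp_path)
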