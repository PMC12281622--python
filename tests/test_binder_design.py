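"""Target orientation, rotation sweep, translation solve, screening, dedup."""

import numpy as np
import pytest

from petei.binder_design import (
    DesignCandidate,
    DesignConfig,
    PlacementSolution,
    complete_design,
    dedupe_designs,
    design_binders,
    orient_target,
    screen_design,
    select_epitope,
    similarity,
    solve_translations,
    sweep_rotations,
)
from petei.geometry import rotation_about_z
from petei.interaction_geometry import InteractionSite, epitope_sites
from petei.loop_harvest import GeometrySignature, LoopDatabase, LoopRecord
from petei.structure_model import Residue, StructureModel, make_atom

from conftest import random_rotation
from oracles import grid_translation_oracle, match_count_at, random_site_instance


def proj(pos, family="hbond_NH_OC", direction=(0, 0, 1)):
    return InteractionSite(position=np.asarray(pos, float), family=family,
                           kind="projection", role="donor",
                           direction=np.asarray(direction, float))


def anch(pos, family="hbond_NH_OC", direction=(0, 0, -1)):
    return InteractionSite(position=np.asarray(pos, float), family=family,
                           kind="anchor", role="acceptor",
                           direction=np.asarray(direction, float))


@pytest.fixture()
def toy_target(rigged):
    return rigged.target, rigged.epitope_selection


class TestOrientTarget:
    def test_epitope_centroid_lands_on_the_z_axis(self, toy_target):
        target, sel = toy_target
        epi = select_epitope(target, sel)
        oriented = orient_target(target, epi, epitope_height=5.0)
        keys = {(r.chain_id, r.seq_id) for r in epi}
        pts = [a.coord for r in oriented.residues()
               for a in r.atoms if (r.chain_id, r.seq_id) in keys and a.is_heavy]
        centroid = np.mean(pts, axis=0)
        np.testing.assert_allclose(centroid[:2], [0.0, 0.0], atol=1e-6)
        assert centroid[2] == pytest.approx(5.0, abs=1e-6)

    def test_orientation_is_idempotent(self, toy_target):
        target, sel = toy_target
        epi = select_epitope(target, sel)
        once = orient_target(target, epi, 5.0)
        twice = orient_target(once, select_epitope(once, sel), 5.0)
        np.testing.assert_allclose(twice.coords(), once.coords(), atol=1e-6)

    def test_orientation_canonicalizes_arbitrary_poses(self, toy_target):
        target, sel = toy_target
        epi = select_epitope(target, sel)
        reference = orient_target(target, epi, 5.0)
        rng = np.random.default_rng(23)
        for _ in range(5):
            moved = target.transform(random_rotation(rng), rng.uniform(-40, 40, 3))
            oriented = orient_target(moved, select_epitope(moved, sel), 5.0)
            np.testing.assert_allclose(oriented.coords(), reference.coords(), atol=1e-5)

    def test_epitope_faces_the_loops_below(self, toy_target):
        target, sel = toy_target
        epi = select_epitope(target, sel)
        oriented = orient_target(target, epi, 5.0)
        keys = {(r.chain_id, r.seq_id) for r in epi}
        epi_z = np.mean([a.coord[2] for r in oriented.residues()
                         for a in r.atoms if (r.chain_id, r.seq_id) in keys])
        rest_z = np.mean([a.coord[2] for r in oriented.residues()
                          for a in r.atoms if (r.chain_id, r.seq_id) not in keys])
        assert epi_z < rest_z


class TestSweepRotations:
    def test_default_step_yields_360_orientations(self, toy_target, rigged):
        target, sel = toy_target
        epi = select_epitope(target, sel)
        oriented = orient_target(target, epi, 5.0)
        keys = {(r.chain_id, r.seq_id) for r in epi}
        oriented_epi = [r for r in oriented.residues() if (r.chain_id, r.seq_id) in keys]
        angles = [a for a, _ in sweep_rotations(oriented, oriented_epi, DesignConfig())]
        assert len(angles) == 360 and angles[0] == 0 and angles[-1] == 359

    def test_angle_zero_equals_direct_enumeration(self, toy_target):
        target, sel = toy_target
        epi = select_epitope(target, sel)
        oriented = orient_target(target, epi, 5.0)
        keys = {(r.chain_id, r.seq_id) for r in epi}
        oriented_epi = [r for r in oriented.residues() if (r.chain_id, r.seq_id) in keys]
        from petei.interaction_geometry import load_packaged_rotamers

        config = DesignConfig(rotation_step=120.0)
        sweep = dict(sweep_rotations(oriented, oriented_epi, config))
        direct = epitope_sites(oriented, oriented_epi, rotamers=load_packaged_rotamers())
        assert len(sweep[0.0]) == len(direct)
        for a, b in zip(sweep[0.0], direct):
            np.testing.assert_allclose(a.position, b.position)

    def test_rotated_sites_are_equivariant(self, toy_target):
        target, sel = toy_target
        epi = select_epitope(target, sel)
        oriented = orient_target(target, epi, 5.0)
        keys = {(r.chain_id, r.seq_id) for r in epi}
        oriented_epi = [r for r in oriented.residues() if (r.chain_id, r.seq_id) in keys]
        config = DesignConfig(rotation_step=90.0)
        sweep = dict(sweep_rotations(oriented, oriented_epi, config))
        R = rotation_about_z(90.0)
        for s0, s90 in zip(sweep[0.0], sweep[90.0]):
            np.testing.assert_allclose(s90.position, s0.position @ R.T, atol=1e-9)


class TestSolveTranslations:
    def test_recovers_a_planted_offset_exactly(self):
        loops = [anch([x, y, 0]) for x, y in [(0, 0), (6, 0), (0, 6), (6, 6)]]
        epis = [proj(l.position - [5.0, 0, 0]) for l in loops]
        sols = solve_translations(epis, loops, DesignConfig())
        assert len(sols) == 1
        np.testing.assert_allclose(sols[0].translation, [5.0, 0, 0], atol=1e-9)
        assert sols[0].n_matches == 4
        assert all(d == pytest.approx(0.0, abs=1e-9) for *_ , d in sols[0].matched_pairs)

    def test_min_interactions_gates_solutions(self):
        loops = [anch([x, y, 0]) for x, y in [(0, 0), (6, 0), (0, 6), (6, 6)]]
        epis = [proj(l.position - [5.0, 0, 0]) for l in loops]
        epis[0].position = epis[0].position + [0, 0, 1.0]  # break one pair
        assert solve_translations(epis, loops, DesignConfig(min_interactions=4)) == []
        sols = solve_translations(epis, loops, DesignConfig(min_interactions=3))
        assert sols and sols[0].n_matches == 3

    def test_sites_are_used_at_most_once_per_solution(self):
        # two projections map onto one anchor; one-to-one forbids double use
        loops = [anch([0, 0, 0]), anch([8, 0, 0]), anch([0, 8, 0])]
        epis = [proj([-5, 0, 0]), proj([-5, 0, 0]),
                proj([3, 0, 0]), proj([-5, 8, 0])]
        sols = solve_translations(epis, loops, DesignConfig(min_interactions=3))
        for sol in sols:
            used_e = [id(e) for e, _, _ in sol.matched_pairs]
            used_l = [id(l) for _, l, _ in sol.matched_pairs]
            assert len(used_e) == len(set(used_e))
            assert len(used_l) == len(set(used_l))

    def test_agrees_with_exhaustive_grid_oracle(self):
        tol = 0.33
        rng = np.random.default_rng(99)
        config = DesignConfig(min_interactions=3)
        for _ in range(10):
            epi_pos, loop_pos, comp, _t = random_site_instance(rng, tol)
            epis = [proj(p) for p in epi_pos]
            loops = [anch(p) for p in loop_pos]
            sols = solve_translations(epis, loops, config)
            grid_pts, grid_counts = grid_translation_oracle(
                epi_pos, loop_pos, comp, tol, config.min_interactions
            )
            if len(grid_pts):
                assert sols
                assert max(s.n_matches for s in sols) >= max(grid_counts)
            for s in sols:
                assert match_count_at(
                    epi_pos, loop_pos, comp, s.translation, tol
                ) == s.n_matches


def _residue_with(atoms, res_name="ALA", seq=1, chain="X"):
    return Residue(res_name, seq, atoms, chain_id=chain)


def _single_chain_model(residues, chain="X", mid="m"):
    return StructureModel(id=mid, chains={chain: residues})


def _loop_of(res_list, loop_id, slot_id):
    seq = "".join(r.one_letter for r in res_list)
    return LoopRecord(loop_id=loop_id, slot_id=slot_id, sequence=seq,
                      residues=res_list, signature=GeometrySignature(tuple([5.0] * 7)))


def _empty_solution():
    return PlacementSolution(rotation=0.0, translation=np.zeros(3), matched_pairs=[])


class TestScreenDesign:
    def _binder_with_backbone_atoms(self, positions):
        residues = [
            _residue_with([make_atom("CA", "C", p, "ALA")], seq=i + 1, chain="L")
            for i, p in enumerate(positions)
        ]
        return _single_chain_model(residues, chain="L", mid="binder")

    def _target_with_backbone_atoms(self, positions):
        residues = [
            _residue_with([make_atom("CA", "C", p, "GLY")], res_name="GLY",
                          seq=i + 1, chain="T")
            for i, p in enumerate(positions)
        ]
        return _single_chain_model(residues, chain="T", mid="target")

    def test_one_backbone_clash_passes_two_fail(self):
        target = self._target_with_backbone_atoms([[0, 0, 0], [8, 0, 0]])
        one = self._binder_with_backbone_atoms([[0, 0, 2.0], [50, 0, 0]])
        two = self._binder_with_backbone_atoms([[0, 0, 2.0], [8, 0, 2.0]])
        sol = _empty_solution()
        assert screen_design(one, target, sol, [])["steric"]
        assert not screen_design(two, target, sol, [])["steric"]

    def test_non_interacting_side_chain_clashes_are_forgiven(self):
        target = self._target_with_backbone_atoms([[0, 0, 0], [8, 0, 0]])
        clashing_side = _single_chain_model(
            [_residue_with(
                [make_atom("CA", "C", [40, 0, 0], "LEU"),
                 make_atom("CD1", "C", [0, 0, 2.0], "LEU"),
                 make_atom("CD2", "C", [8, 0, 2.0], "LEU")],
                res_name="LEU", chain="L")],
            chain="L", mid="binder")
        assert screen_design(clashing_side, target, _empty_solution(), [])["steric"]

    def test_charge_clash_boundary_at_4_2(self):
        target = _single_chain_model(
            [_residue_with([make_atom("NZ", "N", [0, 0, 0], "LYS")],
                           res_name="LYS", chain="T")], chain="T", mid="t")
        def binder_at(d):
            return _single_chain_model(
                [_residue_with([make_atom("NH1", "N", [d, 0, 0], "ARG")],
                               res_name="ARG", chain="L")], chain="L", mid="b")
        assert not screen_design(binder_at(4.1), target, _empty_solution(), [])["charge"]
        assert screen_design(binder_at(4.3), target, _empty_solution(), [])["charge"]

    def test_positive_residue_budget(self):
        def loop_with(names):
            res = [
                _residue_with([make_atom("CA", "C", [i * 5.0, 0, 80], n)],
                              res_name=n, seq=i + 1, chain="L")
                for i, n in enumerate(names)
            ]
            return _loop_of(res, "lp", 1)
        target = self._target_with_backbone_atoms([[0, 0, 0]])
        binder = self._binder_with_backbone_atoms([[50, 0, 0]])
        three = [loop_with(["LYS", "ARG", "LYS"])]
        four = [loop_with(["LYS", "ARG", "LYS", "ARG"])]
        assert screen_design(binder, target, _empty_solution(), three)["positives"]
        assert not screen_design(binder, target, _empty_solution(), four)["positives"]


class TestSimilarityAndDedup:
    def test_similarity_examples(self):
        assert similarity(("a", "b", "c"), ("a", "b", "c")) == 1.0
        assert similarity(("a", "b", "c"), ("a", "b", "d")) == pytest.approx(2 / 3)
        assert similarity(("a", "b", "c"), ("a", "e", "f")) == pytest.approx(1 / 3)

    def _design(self, triple, k):
        return DesignCandidate(
            design_id=f"d{k}",
            loop_ids={1: triple[0], 2: triple[1], 3: triple[2]},
            placement=_empty_solution(),
        )

    def test_greedy_dedup_keeps_first_of_each_cluster(self):
        designs = [self._design(t, i) for i, t in enumerate(
            [("A", "B", "C"), ("A", "B", "D"), ("A", "E", "F")]
        )]
        kept = dedupe_designs(designs, threshold=0.60)
        assert [d.loop_id_tuple() for d in kept] == [("A", "B", "C"), ("A", "E", "F")]

    def test_empty_input_is_empty_output(self):
        assert dedupe_designs([]) == []

    def test_retained_pairs_share_at_most_one_loop(self):
        rng = np.random.default_rng(41)
        pool = [f"L{i}" for i in range(6)]
        designs = [
            self._design(tuple(rng.choice(pool, 3)), i) for i in range(60)
        ]
        kept = dedupe_designs(designs, threshold=0.60)
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                shared = sum(
                    1 for a, b in zip(kept[i].loop_id_tuple(), kept[j].loop_id_tuple())
                    if a == b
                )
                assert shared <= 1


class TestCompletion:
    def test_unique_compatible_loop_completes_the_design(self, rigged):
        db = rigged.database
        partial = DesignCandidate(
            design_id="p", loop_ids={1: db.slots[1][0].loop_id,
                                     2: db.slots[2][0].loop_id, 3: None},
            placement=_empty_solution(),
        )
        target = _single_chain_model(
            [_residue_with([make_atom("CA", "C", [0, 0, 300], "GLY")],
                           res_name="GLY", chain="T")], chain="T")
        out = complete_design(partial, db, rigged.scaffold, rigged.attachment_specs, target)
        assert len(out) == 1
        assert out[0].loop_ids[3] == db.slots[3][0].loop_id

    def test_charge_clashing_completion_is_excluded(self, rigged):
        db = rigged.database
        partial = DesignCandidate(
            design_id="p", loop_ids={1: db.slots[1][0].loop_id,
                                     2: db.slots[2][0].loop_id, 3: None},
            placement=_empty_solution(),
        )
        # park a positive charge on top of the slot-3 loop backbone
        slot3_atom = db.slots[3][0].residues[2].atom("CA").coord
        target = _single_chain_model(
            [_residue_with([make_atom("NZ", "N", slot3_atom + 2.0, "LYS")],
                           res_name="LYS", chain="T")], chain="T")
        # make the slot-3 loop positively charged too
        lys_loop = db.slots[3][0]
        lys_loop.residues[2].res_name = "LYS"
        lys_loop.residues[2].atoms.append(
            make_atom("NZ", "N", slot3_atom + 1.0, "LYS"))
        try:
            out = complete_design(
                partial, db, rigged.scaffold, rigged.attachment_specs, target)
            assert out == []
        finally:
            lys_loop.residues[2].res_name = "GLY"
            lys_loop.residues[2].atoms.pop()

    def test_completions_match_a_brute_force_filter(self, rigged):
        db = rigged.database
        partial = DesignCandidate(
            design_id="p", loop_ids={1: db.slots[1][0].loop_id,
                                     2: db.slots[2][0].loop_id, 3: None},
            placement=_empty_solution(),
        )
        target = _single_chain_model(
            [_residue_with([make_atom("CA", "C", [0, 0, 300], "GLY")],
                           res_name="GLY", chain="T")], chain="T")
        out = complete_design(partial, db, rigged.scaffold, rigged.attachment_specs, target)
        selected = [partial.loop_ids[1], partial.loop_ids[2]]
        expected = [
            lp.loop_id for lp in db.slots[3]
            if all(db.are_compatible(lp.loop_id, s) for s in selected)
        ]
        assert sorted(d.loop_ids[3] for d in out) == sorted(expected)


class TestDesignBinders:
    def test_rigged_benchmark_yields_a_verified_design(self, rigged):
        designs = design_binders(
            rigged.target, rigged.epitope_selection, rigged.database,
            rigged.scaffold, rigged.attachment_specs, rigged.config,
        )
        assert designs
        best = designs[0]
        assert best.placement.n_matches >= 4
        assert all(best.screening.values())
        assert all(lid is not None for lid in best.loop_ids.values())
        assert best.score is not None and best.score.be_bsa is not None
        assert best.score.be_bsa < 0

    def test_unattainable_interaction_bound_yields_nothing(self, rigged):
        config = DesignConfig(
            min_interactions=10, epitope_height=rigged.config.epitope_height,
            rotation_step=5.0,
        )
        designs = design_binders(
            rigged.target, rigged.epitope_selection, rigged.database,
            rigged.scaffold, rigged.attachment_specs, config,
        )
        assert designs == []

    def test_reruns_are_identical(self, rigged):
        def run():
            designs = design_binders(
                rigged.target, rigged.epitope_selection, rigged.database,
                rigged.scaffold, rigged.attachment_specs, rigged.config,
            )
            return [
                (d.design_id, d.loop_id_tuple(), d.placement.rotation,
                 tuple(np.round(d.placement.translation, 12)),
                 d.placement.n_matches, d.score.binding_energy,
                 d.score.buried_surface_area)
                for d in designs
            ]
        assert run() == run()

    def test_empty_database_is_an_error(self, rigged):
        empty = LoopDatabase(slots={1: [], 2: [], 3: []})
        with pytest.raises(ValueError, match="empty"):
            design_binders(rigged.target, rigged.epitope_selection, empty,
                           rigged.scaffold, rigged.attachment_specs)
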