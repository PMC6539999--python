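"""Shell selection, scoring, and the annealed packing engine."""

import copy
import itertools
import json

import numpy as np
import pytest

from focusforge import chemistry
from focusforge.designer import (DesignParams, ScoreWeights, _PackingTables,
                                 designable_positions, mix_seed,
                                 model_variant_complex, redesign,
                                 run_design_stage, score_pose)
from focusforge.errors import SequenceError
from focusforge.fixtures import FixtureRecipe, make_toy_scaffold

from oracles import o_score_model


def _pin_all(scaffold, designable, overrides=None):
    """Restrictions pinning every designable position to wild type."""
    r = {pos: (scaffold.residues[pos].identity,) for pos in designable}
    r.update(overrides or {})
    return r


@pytest.fixture(scope="module")
def first_match(reference_matches):
    return reference_matches[0]


@pytest.fixture(scope="module")
def designable(scaffold, pose, first_match):
    return designable_positions(scaffold, pose, 9.0,
                                fixed=scaffold.fixed_positions,
                                exclude=first_match.assignments.keys())


class TestDesignablePositions:
    def test_band_residues_within_radius(self, scaffold, pose, manifest):
        out = designable_positions(scaffold, pose, 9.0,
                                   fixed=scaffold.fixed_positions)
        decoys = ({tuple(p) for p in manifest["first_shell"]}
                  | {tuple(p) for p in manifest["second_shell"]})
        assert decoys <= set(out)

    def test_fixed_and_excluded_removed(self, scaffold, pose):
        out = designable_positions(scaffold, pose, 9.0,
                                   fixed={("A", 73)}, exclude={("A", 10)})
        assert ("A", 73) not in out and ("A", 10) not in out

    def test_small_radius_empty(self, scaffold, pose):
        assert designable_positions(scaffold, pose, 0.5) == []


class TestScorePose:
    def test_steric_repulsion_zero_at_contact_distance(self):
        rep, _ = chemistry.soft_lj_pair(3.4, 3.4)
        assert rep == 0.0
        rep_in, _ = chemistry.soft_lj_pair(3.0, 3.4)
        assert rep_in > 0.0

    def test_constraint_penalty_zero_inside_range(self, first_match, pose):
        from focusforge.designer import constraint_penalty, _tip_of

        cst = next(c for c in first_match.constraints
                   if c.rotamer_policy == "full")
        pos = next(p for p, a in first_match.assignments.items()
                   if a.constraint == cst.name)
        res = first_match.scaffold.residues[pos]
        asn = first_match.assignments[pos]
        tip = _tip_of(asn.identity, asn.atom_dict(), res)
        assert constraint_penalty(pose, cst, tip) == 0.0

    def test_components_match_independent_evaluator(self, first_match,
                                                    scaffold, designable):
        params = DesignParams(sweeps=0,
                              restrictions=_pin_all(scaffold, designable))
        weights = ScoreWeights(steric=0.9, hbond=1.3, constraint=2.0,
                               reference={"A": 0.25})
        model = redesign(first_match, weights=weights, params=params, seed=0)
        expected = o_score_model(model, weights)
        for key in ("interface", "internal", "constraint", "total"):
            assert model.scores[key] == pytest.approx(expected[key], abs=1e-9)

    def test_total_is_sum_of_components(self, first_match, scaffold,
                                        designable):
        params = DesignParams(sweeps=5,
                              restrictions=_pin_all(scaffold, designable))
        model = redesign(first_match, params=params, seed=3)
        s = model.scores
        assert s["total"] == pytest.approx(
            s["interface"] + s["internal"] + s["constraint"], abs=1e-9)

    def test_atom_order_permutation_invariant(self, first_match, scaffold,
                                              designable):
        params = DesignParams(sweeps=0,
                              restrictions=_pin_all(scaffold, designable))
        model = redesign(first_match, params=params, seed=0)
        shuffled = copy.deepcopy(model)
        shuffled.side_chains = {
            pos: dict(reversed(list(atoms.items())))
            for pos, atoms in model.side_chains.items()}
        a = score_pose(model)
        b = score_pose(shuffled)
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-12)


class TestRedesign:
    def test_zero_sweeps_returns_wild_type_scored(self, first_match, scaffold,
                                                  designable):
        params = DesignParams(sweeps=0,
                              restrictions=_pin_all(scaffold, designable))
        model = redesign(first_match, params=params, seed=0)
        for pos in designable:
            assert model.sequence[pos] == scaffold.residues[pos].identity
        assert set(model.sequence) == set(designable)
        assert "total" in model.scores

    def test_finds_enumerated_optimum_small_system(self, first_match,
                                                   scaffold, designable):
        restr = {pos: ("A",) for pos in designable}
        restr[designable[0]] = ("A", "S")
        restr[designable[1]] = ("A", "V")
        params = DesignParams(sweeps=40, restrictions=restr)
        tables = _PackingTables(
            scaffold, first_match.pose, designable,
            {p: (a.identity, a.atom_dict())
             for p, a in first_match.assignments.items()},
            ScoreWeights(), params)
        n_states = 1
        for pos in designable:
            n_states *= len(tables.options[pos])
        assert n_states <= 64
        best_e = min(tables.energy(dict(zip(designable, combo)))
                     for combo in itertools.product(
                         *[range(len(tables.options[p])) for p in designable]))
        model = redesign(first_match, params=params, seed=11)
        got = {p: next(k for k, o in enumerate(tables.options[p])
                       if o.identity == model.sequence[p]
                       and o.chis == model.rotamers[p])
               for p in designable}
        assert tables.energy(got) == pytest.approx(best_e, abs=1e-9)

    def test_annealer_hits_optimum_in_95_percent_of_runs(self, first_match,
                                                         scaffold, designable):
        restr = {pos: ("A",) for pos in designable}
        restr[designable[0]] = ("A", "S")
        restr[designable[1]] = ("A", "V")
        params = DesignParams(sweeps=25, restrictions=restr)
        tables = _PackingTables(
            scaffold, first_match.pose, designable,
            {p: (a.identity, a.atom_dict())
             for p, a in first_match.assignments.items()},
            ScoreWeights(), params)
        best_e = min(tables.energy(dict(zip(designable, combo)))
                     for combo in itertools.product(
                         *[range(len(tables.options[p])) for p in designable]))
        hits = 0
        for seed in range(100):
            model = redesign(first_match, params=params, seed=seed)
            state = {p: next(k for k, o in enumerate(tables.options[p])
                             if o.identity == model.sequence[p]
                             and o.chis == model.rotamers[p])
                     for p in designable}
            if tables.energy(state) <= best_e + 1e-9:
                hits += 1
        assert hits >= 95

    def test_clashing_wild_type_replaced_by_smaller(self, recipe):
        scaffold, _ = make_toy_scaffold(recipe)
        scaffold = copy.deepcopy(scaffold)
        # drag one decoy's atoms into the ligand to plant a steric problem
        lig = scaffold.anchor_residue
        centroid = np.mean(list(lig.atoms.values()), axis=0)
        victim = scaffold.residues[("A", 20)]
        sc = victim.side_chain_atoms()
        nearest = min(sc.values(),
                      key=lambda x: np.linalg.norm(x - centroid))
        shift = (centroid - nearest)
        shift *= (np.linalg.norm(shift) - 2.0) / np.linalg.norm(shift)
        for name in victim.atoms:
            victim.atoms[name] = victim.atoms[name] + shift
        from focusforge.matcher import find_matches
        from focusforge.ligand import ConformerEnsemble
        from focusforge.fixtures import fixture_constraints, make_toy_ligand
        from focusforge.ligand import template_conformer

        conf = template_conformer(make_toy_ligand())
        csts = [c for c in fixture_constraints(recipe)
                if c.rotamer_policy == "full"]
        matches = find_matches(scaffold, ConformerEnsemble([conf]), csts)
        match = matches[0]
        designable = designable_positions(scaffold, match.pose, 9.0,
                                          fixed=scaffold.fixed_positions,
                                          exclude=match.assignments.keys())
        wt20 = scaffold.residues[("A", 20)].identity
        over = {("A", 20): (wt20, "A")}
        params = DesignParams(sweeps=30,
                              restrictions=_pin_all(scaffold, designable,
                                                    over))
        initial = redesign(match, params=DesignParams(
            sweeps=0, restrictions=_pin_all(scaffold, designable, over)),
            seed=0)
        final = redesign(match, params=params, seed=0)
        assert final.sequence[("A", 20)] == "A"
        assert final.scores["total"] < initial.scores["total"] - 1e-6

    def test_quench_never_worse_than_initial(self, reference_matches,
                                             scaffold):
        for match in reference_matches[:2]:
            designable = designable_positions(
                scaffold, match.pose, 9.0, fixed=scaffold.fixed_positions,
                exclude=match.assignments.keys())
            restr = _pin_all(scaffold, designable,
                             {designable[0]: ("A", "S", "V")})
            initial = redesign(match, params=DesignParams(
                sweeps=0, restrictions=restr), seed=5)
            final = redesign(match, params=DesignParams(
                sweeps=15, restrictions=restr), seed=5)
            assert final.scores["total"] <= initial.scores["total"] + 1e-9

    def test_deterministic_for_same_seed(self, first_match, scaffold,
                                         designable):
        params = DesignParams(sweeps=20,
                              restrictions=_pin_all(
                                  scaffold, designable,
                                  {designable[0]: ("A", "S", "V", "L")}))
        a = redesign(first_match, params=params, seed=77)
        b = redesign(first_match, params=params, seed=77)
        assert a.sequence == b.sequence
        assert a.rotamers == b.rotamers
        assert json.dumps(a.scores, sort_keys=True) == json.dumps(
            b.scores, sort_keys=True)


class TestDesignStage:
    def test_bookkeeping_counts_and_provenance(self, reference_matches,
                                               scaffold):
        designable = designable_positions(
            scaffold, reference_matches[0].pose, 9.0,
            fixed=scaffold.fixed_positions)
        params = DesignParams(sweeps=3,
                              restrictions=_pin_all(scaffold, designable))
        models = run_design_stage(reference_matches[:2], 3, params=params,
                                  base_seed=5)
        assert len(models) == 6
        prov = {(m.provenance["match_id"], m.provenance["repeat"])
                for m in models}
        assert len(prov) == 6
        for m in models:
            assert m.provenance["seed"] == mix_seed(
                5, m.provenance["match_id"], m.provenance["repeat"])

    def test_zero_matches(self):
        assert run_design_stage([], 5) == []

    def test_seed_mixing_is_64_bit(self):
        s = mix_seed(1, "m0001", 3)
        assert 0 <= s < 2**64
        assert s != mix_seed(1, "m0001", 4)
        assert s != mix_seed(2, "m0001", 3)


class TestVariantComplex:
    def test_planted_serine_hbond_reported(self, scaffold, reference_conformer):
        _, report = model_variant_complex(scaffold, {10: "S"},
                                          reference_conformer,
                                          params=DesignParams(sweeps=20))
        pairs = {(r["partner_a"], r["partner_b"]) for r in report}
        assert ("A:10", "ligand:O10") in pairs or ("A:10", "ligand:O11") in pairs

    def test_wild_type_variant_keeps_native_contact(self, scaffold,
                                                    reference_conformer):
        wt = {k[1]: scaffold.residues[k].identity
              for k in scaffold.protein_positions()
              if k not in scaffold.fixed_positions}
        _, report = model_variant_complex(scaffold, wt, reference_conformer,
                                          params=DesignParams(sweeps=20))
        # the fixed native Gln keeps its planted carboxylate H bond
        assert any(r["partner_a"] == "A:73" and r["partner_b"].startswith(
            "ligand:") for r in report)

    def test_all_alanine_shell_loses_ligand_hbonds(self, reference_conformer):
        recipe = FixtureRecipe(seed=4, native_anchor=None)
        scaffold, manifest = make_toy_scaffold(recipe)
        variant = {int(p[1]): "A" for p in
                   (tuple(q) for q in manifest["first_shell"])}
        _, report = model_variant_complex(scaffold, variant,
                                          reference_conformer,
                                          params=DesignParams(sweeps=10))
        assert not [r for r in report if r["partner_b"].startswith("ligand:")]

    def test_unknown_position_rejected(self, scaffold, reference_conformer):
        with pytest.raises(SequenceError):
            model_variant_complex(scaffold, {999: "A"}, reference_conformer)
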