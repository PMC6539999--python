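"""Profiles, curation rules, exact diversity, coverage and mutation counts."""

import math
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from focusforge import library as lib
from focusforge.data import onby_library
from focusforge.errors import (CompletenessError, CurationError,
                               SizeGuardError, SpecError)
from focusforge.fixtures import (ProfileRecipe, curated_library_recipe,
                                 make_toy_profile, raw_profile_recipe)


def _model(identities, scaffold, keys):
    return SimpleNamespace(
        designable=keys, match_positions=[], match_sequence={},
        sequence=dict(zip(keys, identities)), scaffold=scaffold,
        model_id="stub")


def _scaffold(keys, wt="A"):
    return SimpleNamespace(residues={k: SimpleNamespace(identity=wt)
                                     for k in keys})


class TestCompileProfile:
    def test_counts_and_frequencies(self):
        keys = [("A", 1)]
        scaf = _scaffold(keys)
        models = [_model([i], scaf, keys) for i in "AASS"]
        prof = lib.compile_profile(models)
        assert prof.positions[0].counts == {"A": 2, "S": 2}
        assert prof.positions[0].frequencies == {"A": 0.5, "S": 0.5}

    def test_single_model_unit_frequencies(self):
        keys = [("A", 1), ("A", 2)]
        scaf = _scaffold(keys)
        prof = lib.compile_profile([_model(["G", "W"], scaf, keys)])
        for p in prof.positions:
            assert max(p.frequencies.values()) == 1.0

    def test_planted_multinomial_recovered(self, rng):
        keys = [("A", 5)]
        scaf = _scaffold(keys)
        draws = ["A"] * 30 + ["S"] * 12 + ["G"] * 7
        rng.shuffle(draws)
        prof = lib.compile_profile([_model([d], scaf, keys) for d in draws])
        assert prof.positions[0].counts == {"A": 30, "S": 12, "G": 7}
        assert abs(sum(prof.positions[0].frequencies.values()) - 1.0) < 1e-12

    def test_mismatched_designable_sets_rejected(self):
        k1, k2 = [("A", 1)], [("A", 2)]
        with pytest.raises(CompletenessError):
            lib.compile_profile([_model(["A"], _scaffold(k1), k1),
                                 _model(["A"], _scaffold(k2), k2)])


class TestDiversity:
    def test_reference_library_product(self):
        spec = lib.LibrarySpec([(p, w, a) for p, w, a, _ in
                                onby_library.LIBRARY_TABLE])
        assert spec.diversity == 159_252_480
        assert lib.render_scientific(spec.diversity) == "1.6e+08"

    def test_singletons_and_full_alphabet(self):
        ones = lib.LibrarySpec([(i, "A", ("A",)) for i in range(1, 6)])
        assert ones.diversity == 1
        full = lib.LibrarySpec([(i, "A", tuple("ACDEFGHIKLMNPQRSTVWY"))
                                for i in range(1, 27)])
        assert full.diversity == 20**26

    def test_theoretical_sizes(self):
        assert lib.theoretical_diversity(30) == 20**30
        assert lib.theoretical_diversity(0) == 1
        assert round(math.log10(lib.theoretical_diversity(30))) == 39

    def test_empty_set_rejected(self):
        with pytest.raises(SpecError):
            lib.profile_diversity(lib.LibrarySpec([(1, "A", ())]))

    @given(st.lists(st.integers(1, 20), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_exact_for_arbitrary_sizes(self, sizes):
        spec = lib.LibrarySpec([(i, "A", tuple("ACDEFGHIKLMNPQRSTVWY")[:s])
                                for i, s in enumerate(sizes, 1)])
        assert spec.diversity == math.prod(sizes)


class TestCurate:
    def test_low_frequency_removal(self):
        prof = lib.SequenceProfile([lib.ProfilePosition(
            1, "A", {"A": 90, "G": 6, "W": 4})])
        spec, log = lib.curate(prof, lib.CurationRules(min_frequency=0.05))
        assert spec.allowed(1) == ("A", "G")
        assert any(e["rule"] == "low_frequency" and e["identity"] == "W"
                   for e in log)

    def test_similarity_collapse_keeps_one(self):
        prof = lib.SequenceProfile([lib.ProfilePosition(
            1, "A", {"S": 25, "T": 24})])
        spec, log = lib.curate(prof, lib.CurationRules())
        assert spec.allowed(1) == ("S",)  # higher frequency wins

    def test_collapse_tie_alphabetical(self):
        prof = lib.SequenceProfile([lib.ProfilePosition(
            1, "A", {"V": 20, "I": 20, "G": 9})])
        spec, _ = lib.curate(prof, lib.CurationRules())
        assert "I" in spec.allowed(1) and "V" not in spec.allowed(1)

    def test_reference_table_reconstructed_from_planted_profile(self):
        recipe = curated_library_recipe()
        prof = make_toy_profile(recipe)
        assert len(prof.positions) == 26
        spec, _ = lib.curate(prof, recipe.rules())
        want = {p: set(a) for p, _, a, _ in onby_library.LIBRARY_TABLE}
        got = {p: set(a) for p, _, a in spec.positions}
        assert got == want

    def test_wild_type_only_positions_dropped(self):
        prof = lib.SequenceProfile([
            lib.ProfilePosition(1, "A", {"A": 47, "W": 2}),
            lib.ProfilePosition(2, "G", {"G": 30, "Q": 19}),
        ])
        spec, log = lib.curate(prof, lib.CurationRules())
        assert [p for p, _, _ in spec.positions] == [2]
        assert any(e["rule"] == "wild_type_only_dropped" and e["position"] == 1
                   for e in log)

    def test_emptying_a_position_is_an_error(self):
        prof = lib.SequenceProfile([lib.ProfilePosition(
            1, "A", {"W": 1, "G": 1, "S": 48})])
        with pytest.raises(CurationError):
            lib.curate(prof, lib.CurationRules(
                min_frequency=0.05,
                distal_conservative_removals={1: ("S",)}))

    def test_audit_log_replay_round_trip(self):
        recipe = curated_library_recipe()
        prof = make_toy_profile(recipe)
        spec, log = lib.curate(prof, recipe.rules())
        replayed = lib.replay_curation_log(prof, log)
        assert replayed.positions == spec.positions

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_curation_never_increases_diversity(self, seed):
        r = np.random.default_rng(seed)
        positions = []
        letters = "ACDEFGHIKLMNPQRSTVWY"
        for i in range(1, int(r.integers(1, 6)) + 1):
            k = int(r.integers(1, 8))
            idents = r.choice(list(letters), size=k, replace=False)
            counts = {str(x): int(r.integers(1, 30)) for x in idents}
            positions.append(lib.ProfilePosition(i, "A", counts))
        prof = lib.SequenceProfile(positions)
        rules = lib.CurationRules(min_frequency=float(r.uniform(0, 0.2)))
        try:
            spec, _ = lib.curate(prof, rules)
        except CurationError:
            return
        if spec.positions:
            assert lib.profile_diversity(spec) <= lib.profile_diversity(prof)


class TestCoverage:
    def test_reference_transformation_scale(self):
        frac = lib.coverage_fraction(4e9, 159_252_480)
        assert frac > 0.99

    def test_edge_values(self):
        assert lib.coverage_fraction(0, 10) == 0.0
        assert lib.coverage_fraction(1, 1) == 1.0

    def test_monotone_in_n_and_v(self):
        vals_n = [lib.coverage_fraction(n, 1_000_000)
                  for n in (1e4, 1e5, 1e6, 1e7)]
        assert vals_n == sorted(vals_n)
        vals_v = [lib.coverage_fraction(1e6, v)
                  for v in (1e5, 1e6, 1e7, 1e8)]
        assert vals_v == sorted(vals_v, reverse=True)

    def test_limit_approaches_one(self):
        assert lib.coverage_fraction(1e14, 1e8) == pytest.approx(1.0)


class TestReductionsAndMutations:
    def test_orders_of_magnitude(self):
        assert lib.orders_of_magnitude_reduction(20**26, 159_252_480) == 26
        assert lib.orders_of_magnitude_reduction(20**26, 840 * 10**15) == 16
        assert lib.orders_of_magnitude_reduction(10**9, 10**9) == 0

    def test_selected_variant_has_ten_mutations(self):
        assert lib.mutation_count(onby_library.selected_variant(),
                                  onby_library.wild_type()) == 10

    def test_wild_type_zero_and_all_positions_upper_bound(self):
        wt = onby_library.wild_type()
        assert lib.mutation_count(wt, wt) == 0
        flipped = {p: ("A" if w != "A" else "G") for p, w in wt.items()}
        assert lib.mutation_count(flipped, wt) == 17

    def test_fixed_background_excluded_by_default(self):
        var = onby_library.selected_variant()
        assert lib.mutation_count(var, onby_library.wild_type(),
                                  onby_library.FIXED_BACKGROUND,
                                  include_fixed=True) == 11

    def test_missing_reference_raises(self):
        with pytest.raises(KeyError):
            lib.mutation_count({999: "A"}, {1: "A"})


class TestExport:
    def test_two_position_enumeration(self):
        spec = lib.LibrarySpec([(1, "A", ("A", "S")), (2, "G", ("G", "Q"))])
        table, records = lib.export_library(spec, {1: "A", 2: "G"},
                                            enumerate_fasta=True)
        assert len(records) == 4
        assert sorted(str(r.seq) for r in records) == ["AG", "AQ", "SG", "SQ"]
        assert list(table["position"]) == [1, 2]

    def test_size_guard_refuses_reference_library(self):
        spec = lib.LibrarySpec([(p, w, a) for p, w, a, _ in
                                onby_library.LIBRARY_TABLE])
        wt = onby_library.wild_type()
        table, records = lib.export_library(spec, wt)
        assert records is None and len(table) == 17
        with pytest.raises(SizeGuardError):
            lib.export_library(spec, wt, enumerate_fasta=True)

    def test_singleton_spec_with_fixed_background(self):
        spec = lib.LibrarySpec([(1, "A", ("A",))],
                               fixed_background={3: "R"})
        _, records = lib.export_library(spec, {1: "A", 2: "G", 3: "D"},
                                        enumerate_fasta=True)
        assert len(records) == 1
        assert str(records[0].seq) == "AGR"  # D3R applied to every member
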