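"""Unique-mapping extraction, assessment sampling, and contribution statistics."""

import random
from collections import Counter

import pytest

from ontoeval import Alignment, Mapping, Relation, build_index, consensus, contributions, sample_for_assessment, unique_mappings
from ontoeval.consensus import ConsensusSpec, build_vote_table
from ontoeval.unique import UniqueSet, read_verdicts, write_review_sheet
from .conftest import make_ontology


def align(name, mappings):
    return Alignment(mappings, system_name=name)


class TestUniqueMappings:
    def test_identical_systems_have_no_unique_mappings(self):
        a = align("s1", [Mapping("A", "X"), Mapping("B", "Y")])
        b = align("s2", [Mapping("A", "X"), Mapping("B", "Y")])
        assert len(unique_mappings(a, [b])) == 0

    def test_private_mapping_is_unique(self):
        a = align("s1", [Mapping("A", "X"), Mapping("P", "Q")])
        b = align("s2", [Mapping("A", "X")])
        u = unique_mappings(a, [b])
        assert {m.key for m in u.mappings} == {("P", "Q", "=")}

    def test_consensus_entailed_mapping_is_excluded(self):
        """Proposed by no other system, yet derivable through the consensus chain."""
        o1 = make_ontology("O1", subsumptions=[("a", "b")])
        o2 = make_ontology("O2", subsumptions=[("x", "y")])
        consensus2 = align("consensus-v2", [Mapping("a", "x", Relation.EQUIVALENT),
                                            Mapping("b", "y", Relation.EQUIVALENT)])
        idx = build_index(o1, o2, consensus2)
        # b ≡ y is in the consensus; a ⊒ x? test an entailed equivalence: a ≡ x asserted.
        system = align("s1", [Mapping("a", "x", Relation.EQUIVALENT), Mapping("a", "p")])
        u = unique_mappings(system, [align("s2", [Mapping("q", "r")])], idx)
        assert {m.key for m in u.mappings} == {("a", "p", "=")}

    def test_equivalence_only_default_drops_subsumptions(self):
        a = align("s1", [Mapping("A", "X", Relation.SUBSUMED_BY), Mapping("B", "Y")])
        u = unique_mappings(a, [])
        assert {m.key for m in u.mappings} == {("B", "Y", "=")}
        u_all = unique_mappings(a, [], equivalence_only=False)
        assert len(u_all) == 2

    def test_same_pair_different_relation_stays_unique_by_default(self):
        a = align("s1", [Mapping("A", "X", Relation.EQUIVALENT)])
        b = align("s2", [Mapping("A", "X", Relation.SUBSUMED_BY)])
        assert len(unique_mappings(a, [b])) == 1
        assert len(unique_mappings(a, [b], relation_loose=True)) == 0

    def test_family_exclusive_flag(self):
        fams = {"s1": "fam", "s1b": "fam", "s2": "s2"}
        a = align("s1", [Mapping("A", "X")])
        sib = align("s1b", [Mapping("A", "X")])
        assert len(unique_mappings(a, [sib], families=fams)) == 0
        assert len(unique_mappings(a, [sib], families=fams, family_exclusive=True)) == 1

    def test_exclusion_is_symmetric_on_shared_mappings(self):
        shared = Mapping("A", "X")
        a = align("s1", [shared, Mapping("B", "Y")])
        b = align("s2", [shared, Mapping("C", "Z")])
        ua = unique_mappings(a, [b])
        ub = unique_mappings(b, [a])
        assert shared not in ua.mappings and shared not in ub.mappings
        assert len(ua) == 1 and len(ub) == 1

    def test_fixture_private_injection_always_surfaces(self):
        """A system given a private injected mapping shows it in its unique set."""
        from ontoeval.fixtures import FixtureSpec, gen_fixture

        fx = gen_fixture(FixtureSpec(n_classes=80, n_truth_mappings=20, seed=2))
        private = Mapping("O1:0001", "O2:0077", Relation.EQUIVALENT)
        victim = fx.systems[0]
        victim.add(private)
        spec = ConsensusSpec(min_votes=2, families=fx.spec.families)
        table = build_vote_table(fx.systems, spec)
        idx = build_index(fx.o1, fx.o2, consensus(table, 2))
        if not idx.entails(private):
            u = unique_mappings(victim, fx.systems[1:], idx)
            assert private in u.mappings


class TestSampling:
    def test_small_set_returned_whole(self):
        u = UniqueSet("s", {Mapping(f"A{i}", f"B{i}") for i in range(7)})
        assert len(sample_for_assessment(u, cap=30, seed=1)) == 7

    def test_cap_respected_and_deterministic(self):
        u = UniqueSet("s", {Mapping(f"A{i}", f"B{i}") for i in range(100)})
        s1 = sample_for_assessment(u, cap=30, seed=5)
        s2 = sample_for_assessment(u, cap=30, seed=5)
        assert len(s1) == 30 and s1 == s2
        assert sample_for_assessment(u, cap=30, seed=6) != s1

    def test_empty_set_gives_empty_sample(self):
        assert sample_for_assessment(UniqueSet("s", set()), cap=30, seed=0) == []

    def test_sampling_is_uniform(self):
        """Each of 10 elements appears in a 3-draw sample ~30% of the time."""
        u = UniqueSet("s", {Mapping(f"A{i}", f"B{i}") for i in range(10)})
        counts = Counter()
        n_draws = 10_000
        for seed in range(n_draws):
            for m in sample_for_assessment(u, cap=3, seed=seed):
                counts[m.key] += 1
        # binomial(10^4, 0.3): sd ≈ 45.8; allow 5 sd
        for key, c in counts.items():
            assert abs(c - 3000) < 5 * 46, (key, c)


class TestReviewSheet:
    def test_roundtrip_with_verdicts(self):
        sample = [Mapping("A", "X"), Mapping("B", "Y"), Mapping("C", "Z")]
        sheet = write_review_sheet(sample, {"A": "alpha"}, {"X": "ex"})
        lines = sheet.splitlines()
        assert lines[0].split("\t") == ["source", "source_label", "target", "target_label", "relation", "verdict"]
        filled = sheet.replace("A\talpha\tX\tex\t=\t", "A\talpha\tX\tex\t=\tcorrect")
        filled = filled.replace("B\t\tY\t\t=\t", "B\t\tY\t\t=\tincorrect")
        assert read_verdicts(filled) == (2, 1)  # third row left blank -> not assessed

    def test_bad_verdict_rejected(self):
        sheet = write_review_sheet([Mapping("A", "X")]).replace("=\t", "=\tmaybe")
        with pytest.raises(ValueError, match="maybe"):
            read_verdicts(sheet)


class TestContributions:
    def test_published_arithmetic_rows(self):
        """Contribution arithmetic reproduces the printed assessment tables."""
        recs = {r.system_name: r for r in contributions(
            [("PhenoMF", 89, 1.00), ("PhenoMP", 80, 1.00), ("rest", 1225 - 89 - 80, 0.9)]
        )}
        assert round(100 * recs["PhenoMF"].positive_contribution, 2) == 7.27
        assert recs["PhenoMF"].negative_contribution == 0.0
        assert round(100 * recs["PhenoMP"].positive_contribution, 2) == 6.53

        recs = {r.system_name: r for r in contributions(
            [("LogMapLt", 7, 0.50), ("PhenoMF", 3, 1.00), ("rest", 878 - 10, 0.8)]
        )}
        assert round(100 * recs["LogMapLt"].positive_contribution, 2) == 0.40
        assert round(100 * recs["LogMapLt"].negative_contribution, 2) == 0.40
        assert round(100 * recs["PhenoMF"].positive_contribution, 2) == 0.34

    def test_counts_form_accepted(self):
        (rec, total) = contributions([("s", 40, 30, 15)])
        assert rec.precision_est == 0.5
        assert rec.positive_contribution == rec.negative_contribution == 0.5

    def test_conservation_on_random_batches(self):
        """Σ(PC + NC) = 1 on 1000 random batches (algebraic identity)."""
        rng = random.Random(13)
        for _ in range(1000):
            batch = [(f"s{i}", rng.randrange(0, 50), round(rng.random(), 3))
                     for i in range(rng.randrange(1, 8))]
            if sum(n for _, n, _ in batch) == 0:
                continue
            records = contributions(batch)
            total = records[-1]
            assert total.system_name == "Total"
            assert total.positive_contribution + total.negative_contribution == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_count_and_precision(self):
        base = [("a", 10, 0.5), ("b", 20, 0.5)]
        pc = lambda recs, name: next(r for r in recs if r.system_name == name).positive_contribution
        assert pc(contributions([("a", 15, 0.5), ("b", 20, 0.5)]), "a") > pc(contributions(base), "a")
        assert pc(contributions([("a", 10, 0.7), ("b", 20, 0.5)]), "a") > pc(contributions(base), "a")

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            contributions([("a", 0, 1.0)])
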