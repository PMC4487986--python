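"""Reciprocal-best-hit filters, tie rules, reciprocity and overrides."""

import random

import pytest

from cnvortho._util import ConfigError, InputError
from cnvortho.alignment import AlignmentHit, ProteinEntry, get_matrix
from cnvortho.rbh import (
    HitFilterPolicy,
    Override,
    apply_overrides,
    best_hit_set,
    filter_hits,
    reciprocal_orthologs,
)

from oracles import rbh_oracle

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def hit(subject, bit=100.0, ev=1e-20, qcov=0.9, scov=0.9):
    return AlignmentHit(
        query_gene="q", subject_gene=subject, raw_score=bit,
        query_length=100, subject_length=100,
        query_coverage=qcov, subject_coverage=scov,
        bit_score=bit, evalue=ev,
    )


def mutate(seq, n_subs, rng):
    seq = list(seq)
    for pos in rng.sample(range(len(seq)), n_subs):
        seq[pos] = rng.choice([r for r in RESIDUES if r != seq[pos]])
    return "".join(seq)


def random_proteome(n, species, rng, length=60):
    return [
        ProteinEntry(
            gene_id=f"{species}{i:02d}",
            species=species,
            sequence="".join(rng.choices(RESIDUES, k=length)),
        )
        for i in range(n)
    ]


class TestFilterHits:
    policy = HitFilterPolicy()

    def test_evalue_threshold(self):
        assert filter_hits([hit("a", ev=1e-5)], self.policy) == []
        assert len(filter_hits([hit("a", ev=1e-7)], self.policy)) == 1

    def test_either_sequence_coverage(self):
        h = hit("a", qcov=0.49, scov=0.51)
        assert len(filter_hits([h], self.policy)) == 1
        both = HitFilterPolicy(coverage_mode="both_sequences")
        assert filter_hits([h], both) == []

    def test_both_below_coverage_removed(self):
        assert filter_hits([hit("a", qcov=0.4, scov=0.3)], self.policy) == []

    def test_empty_input(self):
        assert filter_hits([], self.policy) == []

    def test_tightening_never_adds(self):
        rng = random.Random(5)
        hits = [
            hit(f"s{i}", ev=10 ** -rng.randint(4, 12),
                qcov=rng.random(), scov=rng.random())
            for i in range(50)
        ]
        loose = {h.subject_gene for h in filter_hits(hits, HitFilterPolicy())}
        tight_e = {
            h.subject_gene
            for h in filter_hits(hits, HitFilterPolicy(max_evalue=1e-9))
        }
        tight_c = {
            h.subject_gene
            for h in filter_hits(hits, HitFilterPolicy(min_coverage=0.8))
        }
        assert tight_e <= loose and tight_c <= loose


class TestBestHitSet:
    def test_exact_ties_only_by_default(self):
        hits = [hit("A", 120.0), hit("B", 120.0), hit("C", 80.0)]
        assert best_hit_set(hits, HitFilterPolicy()) == {"A", "B"}

    def test_duplicate_mode_relative_tolerance(self):
        hits = [hit("A", 120.0), hit("B", 118.0)]
        policy = HitFilterPolicy(tie_tolerance=0.02, duplicate_mode=True)
        assert best_hit_set(hits, policy) == {"A", "B"}  # 118 >= 120*0.98
        assert best_hit_set(hits, HitFilterPolicy()) == {"A"}

    def test_duplicate_mode_default_tolerance(self):
        assert HitFilterPolicy(duplicate_mode=True).effective_tie_tolerance == 0.02
        assert HitFilterPolicy().effective_tie_tolerance == 0.0

    def test_no_hits(self):
        assert best_hit_set([], HitFilterPolicy()) == set()


class TestReciprocalOrthologs:
    def test_planted_one_to_one_low_divergence(self):
        rng = random.Random(11)
        human = random_proteome(3, "h", rng)
        target = [
            ProteinEntry(
                gene_id=f"t{i:02d}", species="t",
                sequence=mutate(p.sequence, 6, rng),
            )
            for i, p in enumerate(human)
        ]
        got = reciprocal_orthologs(human, target)
        assert {(a.human_gene, a.homologue_ids()) for a in got} == {
            ("h00", ("t00",)), ("h01", ("t01",)), ("h02", ("t02",)),
        }
        oracle = rbh_oracle(human, target, HitFilterPolicy(), get_matrix())
        assert {a.human_gene: set(a.homologue_ids()) for a in got} == oracle

    def test_asymmetric_best_hit_yields_no_assignment(self):
        rng = random.Random(3)
        base = "".join(rng.choices(RESIDUES, k=60))
        # t0 is h's best hit; t0's best hit is h_prime (closer to t0)
        t0 = mutate(base, 10, rng)
        h = mutate(t0, 8, rng)
        h_prime = mutate(t0, 2, rng)
        human = [
            ProteinEntry("h", "human", h),
            ProteinEntry("h_prime", "human", h_prime),
        ]
        target = [ProteinEntry("t0", "target", t0)]
        got = reciprocal_orthologs(human, target)
        assert [a.human_gene for a in got] == ["h_prime"]

    def test_identical_duplicate_gives_exact_tie(self):
        rng = random.Random(4)
        human = random_proteome(2, "h", rng)
        dup = ProteinEntry("t00_copy", "t", human[0].sequence)
        target = [
            ProteinEntry("t00", "t", human[0].sequence),
            dup,
            ProteinEntry("t01", "t", mutate(human[1].sequence, 5, rng)),
        ]
        got = {a.human_gene: a for a in reciprocal_orthologs(human, target)}
        assert got["h00"].homologue_ids() == ("t00", "t00_copy")
        assert got["h00"].tie is True
        assert got["h01"].tie is False

    def test_duplicate_gene_id_rejected(self):
        p = ProteinEntry("g", "h", "ACDEFGHIKL")
        with pytest.raises(InputError):
            reciprocal_orthologs([p, p], [ProteinEntry("t", "t", "ACDEFGHIKL")])

    def test_matches_bruteforce_oracle_on_random_instances(self):
        for seed in range(6):
            rng = random.Random(seed)
            n = rng.randint(4, 10)
            human = random_proteome(n, "h", rng, length=50)
            target = []
            for i, p in enumerate(human):
                if rng.random() < 0.75:  # gene loss
                    target.append(
                        ProteinEntry(
                            f"t{i:02d}", "t", mutate(p.sequence, rng.randint(0, 12), rng)
                        )
                    )
            policy = HitFilterPolicy()
            got = {
                a.human_gene: set(a.homologue_ids())
                for a in reciprocal_orthologs(human, target, policy)
            }
            expected = rbh_oracle(human, target, policy, get_matrix())
            assert got == expected, seed

    def test_deterministic_under_input_permutation(self):
        rng = random.Random(9)
        human = random_proteome(5, "h", rng)
        target = [
            ProteinEntry(f"t{i:02d}", "t", mutate(p.sequence, 4, rng))
            for i, p in enumerate(human)
        ]
        a1 = reciprocal_orthologs(human, target)
        a2 = reciprocal_orthologs(list(reversed(human)), list(reversed(target)))
        assert a1 == a2


class TestOverrides:
    base = [
        # an existing RBH assignment
        __import__("cnvortho").OrthologAssignment(
            human_gene="HIRA", species="worm", homologues=(("K10D2.1", 33.0),)
        )
    ]

    def test_override_added_for_missing_assignment(self):
        ov = Override("MED15", "worm", "mdt-15", "functional homology", 26.0)
        out = apply_overrides(self.base, [ov], known_species={"worm"})
        med = next(a for a in out if a.human_gene == "MED15")
        assert med.provenance == "override"
        assert med.homologue_ids() == ("mdt-15",)

    def test_empty_override_list_is_noop(self):
        assert apply_overrides(self.base, []) == sorted(
            self.base, key=lambda a: (a.species, a.human_gene)
        )

    def test_override_never_replaces_rbh(self):
        ov = Override("HIRA", "worm", "something-else")
        out = apply_overrides(self.base, [ov])
        hira = next(a for a in out if a.human_gene == "HIRA")
        assert hira.homologue_ids() == ("K10D2.1",)
        assert hira.provenance == "rbh"

    def test_idempotent(self):
        ov = Override("MED15", "worm", "mdt-15", similarity=26.0)
        once = apply_overrides(self.base, [ov])
        twice = apply_overrides(once, [ov])
        assert once == twice

    def test_unknown_species_rejected(self):
        ov = Override("MED15", "martian", "mdt-15")
        with pytest.raises(ConfigError):
            apply_overrides(self.base, [ov], known_species={"worm"})
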