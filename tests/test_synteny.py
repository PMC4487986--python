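"""Synteny cluster detection: fixtures, maximality, and enumeration oracle."""

import random

import pytest

from cnvortho._util import InputError
from cnvortho.pipeline import _table_to_assignments
from cnvortho.rbh import OrthologAssignment
from cnvortho.synteny import (
    GenePlacement,
    assign_ordinals,
    chromosome_span,
    find_clusters,
    validate_cluster,
)

from oracles import synteny_oracle


def placements(species, layout):
    """layout: {chrom: [gene ids in order]} -> GenePlacement list."""
    out = []
    for chrom, genes in layout.items():
        for k, g in enumerate(genes):
            start = 1000 + k * 100
            out.append(GenePlacement(species, g, chrom, start, start + 50))
    return out


def simple_assignments(mapping, species="sp"):
    """mapping: human gene -> homologue id or tuple of ids."""
    out = []
    for human, homs in mapping.items():
        homs = (homs,) if isinstance(homs, str) else homs
        out.append(
            OrthologAssignment(
                human_gene=human,
                species=species,
                homologues=tuple((h, 50.0) for h in homs),
                tie=len(homs) > 1,
            )
        )
    return out


def human_placements(genes):
    return [
        GenePlacement("human", g, "chr22", 1000 + i * 100, 1050 + i * 100)
        for i, g in enumerate(genes)
    ]


class TestFixtureClusters:
    def test_mouse_core_run_hira_to_gnb1l(self, conservation_table, placements):
        clusters = find_clusters(
            _table_to_assignments(conservation_table, "mouse"),
            placements["human"],
            placements["mouse"],
        )
        big = max(clusters, key=len)
        genes = list(big.human_genes)
        i = genes.index("HIRA")
        assert genes[i : i + 10] == [
            "HIRA", "MRPL40", "C22orf39", "UFD1L", "CDC45",
            "CLDN5", "SEPT5", "GP1BB", "TBX1", "GNB1L",
        ]

    def test_zebrafish_span_is_8_chromosomes(self, conservation_table, placements):
        n, tallies = chromosome_span(
            _table_to_assignments(conservation_table, "zebrafish"),
            placements["zebrafish"],
        )
        assert n == 8
        assert sum(tallies.values()) == 42  # 37 genes, 5 with two copies

    def test_zebrafish_tbx1_tango2_cluster(self, conservation_table, placements):
        clusters = find_clusters(
            _table_to_assignments(conservation_table, "zebrafish"),
            placements["human"],
            placements["zebrafish"],
        )
        genes_by_chrom = {
            c.target_chromosome: list(c.human_genes) for c in clusters
        }
        assert genes_by_chrom["chr5"] == [
            "TBX1", "GNB1L", "TXNRD2", "COMT", "ARVCF", "TANGO2",
        ]

    def test_every_fixture_cluster_validates(self, conservation_table, placements):
        for sp in ("worm", "fly", "zebrafish", "mouse"):
            clusters = find_clusters(
                _table_to_assignments(conservation_table, sp),
                placements["human"],
                placements[sp],
            )
            for c in clusters:
                validate_cluster(c, placements[sp])


class TestClusterRules:
    def test_single_conserved_gene_no_cluster(self):
        a = simple_assignments({"G2": "t2"})
        hp = human_placements(["G1", "G2", "G3"])
        tp = placements("sp", {"c1": ["t2"]})
        assert find_clusters(a, hp, tp) == []

    def test_chromosome_switch_breaks_cluster(self):
        a = simple_assignments({"G1": "t1", "G2": "t2", "G3": "t3"})
        hp = human_placements(["G1", "G2", "G3"])
        tp = placements("sp", {"c1": ["t1", "t2"], "c2": ["t3"]})
        clusters = find_clusters(a, hp, tp)
        assert len(clusters) == 1
        assert clusters[0].human_genes == ("G1", "G2")

    def test_gap_bound_respected(self):
        a = simple_assignments({"G1": "t1", "G2": "t2"})
        hp = human_placements(["G1", "G2"])
        # 4 intervening genes between t1 and t2 exceeds max_gap=3
        tp = placements("sp", {"c1": ["t1", "x1", "x2", "x3", "x4", "t2"]})
        assert find_clusters(a, hp, tp, max_gap=3) == []
        assert len(find_clusters(a, hp, tp, max_gap=4)) == 1

    def test_raising_max_gap_never_shrinks_clusters(self):
        rng = random.Random(0)
        for _ in range(10):
            genes = [f"G{i}" for i in range(8)]
            homs = {g: f"t{i}" for i, g in enumerate(genes)}
            order = [homs[g] for g in genes] + [f"x{i}" for i in range(6)]
            rng.shuffle(order)
            a = simple_assignments(homs)
            hp = human_placements(genes)
            tp = placements("sp", {"c1": order})
            small = find_clusters(a, hp, tp, max_gap=1)
            large = find_clusters(a, hp, tp, max_gap=4)
            for c in small:
                assert any(
                    set(c.human_genes) <= set(c2.human_genes) for c2 in large
                )

    def test_tied_homologue_may_satisfy_constraint(self):
        # G2 has two copies: one far away, one adjacent to t1 and t3
        a = simple_assignments({"G1": "t1", "G2": ("t2a", "t2b"), "G3": "t3"})
        hp = human_placements(["G1", "G2", "G3"])
        tp = placements(
            "sp", {"c1": ["t1", "t2a", "t3"] + [f"x{i}" for i in range(8)] + ["t2b"]}
        )
        clusters = find_clusters(a, hp, tp)
        assert len(clusters) == 1
        assert clusters[0].human_genes == ("G1", "G2", "G3")
        assert clusters[0].homologues == ("t1", "t2a", "t3")
        assert clusters[0].collinear

    def test_collinear_flag_false_for_shuffled_order(self):
        a = simple_assignments({"G1": "t1", "G2": "t2", "G3": "t3"})
        hp = human_placements(["G1", "G2", "G3"])
        tp = placements("sp", {"c1": ["t2", "t1", "t3"]})
        clusters = find_clusters(a, hp, tp)
        assert len(clusters) == 1
        assert clusters[0].collinear is False

    def test_missing_placement_names_gene(self):
        a = simple_assignments({"G1": "t1", "G2": "t2"})
        hp = human_placements(["G1", "G2"])
        tp = placements("sp", {"c1": ["t1"]})
        with pytest.raises(InputError, match="t2"):
            find_clusters(a, hp, tp)

    def test_matches_enumeration_oracle_on_random_instances(self):
        for seed in range(8):
            rng = random.Random(seed)
            n = rng.randint(5, 12)
            genes = [f"G{i}" for i in range(n)]
            conserved = [g for g in genes if rng.random() < 0.8]
            chroms = ["c1", "c2", "c3"]
            layout = {c: [] for c in chroms}
            homs = {}
            for g in conserved:
                copies = ["%s_t" % g]
                if rng.random() < 0.2:
                    copies.append("%s_t2" % g)
                homs[g] = tuple(copies)
                for cp in copies:
                    layout[rng.choice(chroms)].append(cp)
            for c in chroms:  # pad with unrelated genes and shuffle
                layout[c] += [f"{c}_x{i}" for i in range(rng.randint(0, 4))]
                rng.shuffle(layout[c])
            a = simple_assignments({g: homs[g] for g in conserved})
            hp = human_placements(genes)
            tp = placements("sp", layout)
            max_gap = rng.randint(0, 3)
            got = {
                (c.human_genes, c.target_chromosome)
                for c in find_clusters(a, hp, tp, max_gap)
            }
            # build oracle candidate structure in conserved order
            ordinals = assign_ordinals(tp)
            conserved_order = [g for g in genes if g in homs]
            cand = []
            for g in conserved_order:
                per = {}
                for cp in homs[g]:
                    chrom, rank = ordinals[cp]
                    per.setdefault(chrom, []).append(rank)
                cand.append(per)
            expected = {
                (tuple(conserved_order[s : e + 1]), chrom)
                for s, e, chrom in synteny_oracle(cand, len(cand), max_gap)
            }
            assert got == expected, seed

    def test_reported_clusters_are_maximal(self, conservation_table, placements):
        # no cluster can be extended by an adjacent conserved gene
        for sp in ("zebrafish", "mouse"):
            assignments = _table_to_assignments(conservation_table, sp)
            hp = placements["human"]
            tp = placements[sp]
            pos = {p.gene_id: p.start for p in hp}
            order = [a.human_gene for a in sorted(assignments, key=lambda a: pos[a.human_gene])]
            ordinals = assign_ordinals(tp)
            by_gene = {a.human_gene: a for a in assignments}
            for c in find_clusters(assignments, hp, tp):
                first = order.index(c.human_genes[0])
                last = order.index(c.human_genes[-1])
                for adj, anchor in ((first - 1, c.homologues[0]), (last + 1, c.homologues[-1])):
                    if not 0 <= adj < len(order):
                        continue
                    anchor_rank = ordinals[anchor][1]
                    extendable = any(
                        ordinals[h][0] == c.target_chromosome
                        and abs(ordinals[h][1] - anchor_rank) - 1 <= c.max_gap
                        for h in by_gene[order[adj]].homologue_ids()
                    )
                    assert not extendable, (sp, c.human_genes, order[adj])


class TestChromosomeSpan:
    def test_all_on_one_chromosome(self):
        a = simple_assignments({"G1": "t1", "G2": "t2"})
        tp = placements("sp", {"c1": ["t1", "t2"]})
        n, tallies = chromosome_span(a, tp)
        assert n == 1 and tallies == {"c1": 2}

    def test_no_assignments(self):
        n, tallies = chromosome_span([], placements("sp", {"c1": ["t1"]}))
        assert n == 0 and tallies == {}
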