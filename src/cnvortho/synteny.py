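"""Synteny cluster detection.

Finds conserved clusters: maximal runs of region genes, consecutive in
their human positional order among conserved genes, whose homologues lie
on one target chromosome with at most ``max_gap`` intervening target genes
between neighbouring homologues. Gaps are measured in gene ordinals (rank
along the chromosome), not base pairs. Order within a cluster is not
required to be preserved; monotone homologue order is reported as the
``collinear`` flag. For tied multi-homologue assignments a cluster may use
whichever copy satisfies the constraints; the chosen copy is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._util import InputError
from .rbh import OrthologAssignment

DEFAULT_MAX_GAP = 3


@dataclass(frozen=True)
class GenePlacement:
    """A gene's location in one species' genome."""

    species: str
    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(
                f"placement {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass(frozen=True)
class SyntenyCluster:
    """A run of >= 2 region genes with co-located homologues."""

    species: str
    human_genes: tuple[str, ...]  # ordered by human region position
    homologues: tuple[str, ...]  # chosen homologue per member gene
    target_chromosome: str
    max_gap: int
    collinear: bool

    def __len__(self) -> int:
        return len(self.human_genes)


def assign_ordinals(
    placements: Iterable[GenePlacement],
) -> dict[str, tuple[str, int]]:
    """Map gene_id -> (chromosome, ordinal), ranking genes along each
    chromosome by start position (ties by gene id)."""
    by_chrom: dict[str, list[GenePlacement]] = {}
    for p in placements:
        by_chrom.setdefault(p.chromosome, []).append(p)
    out: dict[str, tuple[str, int]] = {}
    for chrom, plist in by_chrom.items():
        plist.sort(key=lambda p: (p.start, p.gene_id))
        for rank, p in enumerate(plist):
            if p.gene_id in out:
                raise InputError(f"duplicate placement for gene {p.gene_id!r}")
            out[p.gene_id] = (chrom, rank)
    return out


def _conserved_order(
    assignments: Sequence[OrthologAssignment],
    placements_human: Sequence[GenePlacement],
) -> list[OrthologAssignment]:
    pos = {p.gene_id: p.start for p in placements_human}
    for a in assignments:
        if a.human_gene not in pos:
            raise InputError(f"no human placement for gene {a.human_gene!r}")
    return sorted(assignments, key=lambda a: (pos[a.human_gene], a.human_gene))


def _gap_ok(o1: int, o2: int, max_gap: int) -> bool:
    return abs(o1 - o2) - 1 <= max_gap


def find_clusters(
    assignments: Sequence[OrthologAssignment],
    placements_human: Sequence[GenePlacement],
    placements_target: Sequence[GenePlacement],
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[SyntenyCluster]:
    """All maximal gap-bounded synteny clusters of size >= 2.

    Clusters are detected per target chromosome by chaining: an interval of
    consecutive conserved genes is feasible on chromosome c when a copy of
    each gene's homologue set can be chosen on c such that neighbouring
    choices are within the ordinal gap bound. All maximal feasible
    intervals are reported; overlapping clusters on different chromosomes
    are all kept, matching how comparative maps draw one bar per run.
    """
    if max_gap < 0:
        raise InputError("max_gap must be >= 0")
    if not assignments:
        return []
    species = assignments[0].species
    ordinals = assign_ordinals(placements_target)
    order = _conserved_order(assignments, placements_human)
    # candidate (ordinal) placements per conserved gene per chromosome
    candidates: list[dict[str, list[tuple[str, int]]]] = []
    for a in order:
        per_chrom: dict[str, list[tuple[str, int]]] = {}
        for hom in a.homologue_ids():
            if hom not in ordinals:
                raise InputError(
                    f"no target placement for homologue {hom!r} "
                    f"of {a.human_gene!r}"
                )
            chrom, rank = ordinals[hom]
            per_chrom.setdefault(chrom, []).append((hom, rank))
        candidates.append(per_chrom)

    chroms = sorted({c for per in candidates for c in per})
    intervals: list[tuple[int, int, str]] = []  # (start_idx, end_idx, chrom)
    for chrom in chroms:
        feasible_end: dict[int, int] = {}
        for s in range(len(order)):
            if chrom not in candidates[s]:
                continue
            # chain DP: extend interval [s, e] while a consistent copy
            # choice exists; states = reachable copies of the last gene
            states = set(candidates[s][chrom])
            e = s
            while e + 1 < len(order):
                nxt = candidates[e + 1].get(chrom, [])
                new_states = {
                    (hom, rank)
                    for hom, rank in nxt
                    if any(_gap_ok(rank, r, max_gap) for _, r in states)
                }
                if not new_states:
                    break
                states = new_states
                e += 1
            feasible_end[s] = e
        for s, e in feasible_end.items():
            if e - s + 1 < 2:
                continue
            contained = any(
                s2 <= s and e <= feasible_end[s2]
                for s2 in feasible_end
                if s2 != s
            )
            if not contained:
                intervals.append((s, e, chrom))

    clusters = []
    for s, e, chrom in sorted(intervals):
        chain = _backtrack_chain(candidates, s, e, chrom, max_gap)
        ranks = [ordinals[h][1] for h in chain]
        collinear = _is_monotone(ranks)
        clusters.append(
            SyntenyCluster(
                species=species,
                human_genes=tuple(a.human_gene for a in order[s : e + 1]),
                homologues=tuple(chain),
                target_chromosome=chrom,
                max_gap=max_gap,
                collinear=collinear,
            )
        )
    return clusters


def _backtrack_chain(candidates, s, e, chrom, max_gap) -> list[str]:
    """Recover one consistent copy choice for a feasible interval,
    preferring collinear (and then lexicographically smallest) chains."""
    layers = [sorted(candidates[i][chrom]) for i in range(s, e + 1)]
    # forward DP keeping, for each state, the best predecessor
    best: list[dict[tuple[str, int], tuple[int, list[str]]]] = []
    first = {st: (0, [st[0]]) for st in layers[0]}
    best.append(first)
    for layer in layers[1:]:
        cur: dict[tuple[str, int], tuple[int, list[str]]] = {}
        for hom, rank in layer:
            options = []
            for (p_hom, p_rank), (breaks, chain) in best[-1].items():
                if not _gap_ok(rank, p_rank, max_gap):
                    continue
                # count order breaks to prefer collinear chains
                step_break = 0
                if len(chain) >= 2:
                    prev_dir = 1 if p_rank >= _rank_of(chain[-2], layers, best) else -1
                    step_dir = 1 if rank >= p_rank else -1
                    step_break = int(step_dir != prev_dir)
                options.append((breaks + step_break, chain + [hom]))
            if options:
                cur[(hom, rank)] = min(options, key=lambda t: (t[0], t[1]))
        best.append(cur)
    final = min(best[-1].values(), key=lambda t: (t[0], t[1]))
    return final[1]


def _rank_of(hom: str, layers, best) -> int:
    for layer in layers:
        for h, r in layer:
            if h == hom:
                return r
    return 0


def _is_monotone(ranks: Sequence[int]) -> bool:
    inc = all(b >= a for a, b in zip(ranks, ranks[1:]))
    dec = all(b <= a for a, b in zip(ranks, ranks[1:]))
    return inc or dec


def validate_cluster(
    cluster: SyntenyCluster,
    placements_target: Sequence[GenePlacement],
) -> None:
    """Re-check a cluster's own invariants; raises InputError on violation."""
    if len(cluster) < 2:
        raise InputError("cluster smaller than 2 genes")
    ordinals = assign_ordinals(placements_target)
    ranks = []
    for hom in cluster.homologues:
        chrom, rank = ordinals[hom]
        if chrom != cluster.target_chromosome:
            raise InputError(
                f"homologue {hom} not on {cluster.target_chromosome}"
            )
        ranks.append(rank)
    for r1, r2 in zip(ranks, ranks[1:]):
        if not _gap_ok(r1, r2, cluster.max_gap):
            raise InputError("adjacent homologues exceed the gap bound")
    if cluster.collinear != _is_monotone(ranks):
        raise InputError("collinear flag inconsistent with homologue order")


def chromosome_span(
    assignments: Sequence[OrthologAssignment],
    placements_target: Sequence[GenePlacement],
) -> tuple[int, dict[str, int]]:
    """Distinct target chromosomes carrying >= 1 homologue, with tallies."""
    ordinals = assign_ordinals(placements_target)
    tallies: dict[str, int] = {}
    for a in assignments:
        for hom in a.homologue_ids():
            if hom in ordinals:
                chrom = ordinals[hom][0]
                tallies[chrom] = tallies.get(chrom, 0) + 1
    return len(tallies), dict(sorted(tallies.items()))


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def read_placements_tsv(path: str | Path) -> list[GenePlacement]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["species", "gene_id", "chrom", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"placement table missing columns: {missing}")
    return [
        GenePlacement(
            species=str(r["species"]),
            gene_id=str(r["gene_id"]),
            chromosome=str(r["chrom"]),
            start=int(r["start"]),
            end=int(r["end"]),
        )
        for _, r in df.iterrows()
    ]


def clusters_to_frame(clusters: Sequence[SyntenyCluster]) -> pd.DataFrame:
    rows = [
        {
            "species": c.species,
            "target_chromosome": c.target_chromosome,
            "n_genes": len(c),
            "human_genes": ";".join(c.human_genes),
            "homologues": ";".join(c.homologues),
            "collinear": c.collinear,
            "max_gap": c.max_gap,
        }
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "target_chromosome",
            "n_genes",
            "human_genes",
            "homologues",
            "collinear",
            "max_gap",
        ],
    )
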