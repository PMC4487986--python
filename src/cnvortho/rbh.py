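"""Reciprocal-best-hit (RBH) orthology.

Turns all-vs-all local-alignment hits between a query (human) proteome and
a target proteome into ortholog assignments: a human gene h is assigned
target gene g iff g is among h's best filtered hits and h is among g's
best filtered hits in the opposite direction. Exact bit-score ties yield
multi-homologue assignments; a relative score tolerance (duplicate mode)
widens ties for genomes with recent whole-genome duplication, where
paralog pairs score "very similar" but not identical. Curated
functional-homology overrides can add assignments the sequence filters
reject; overrides are additive only and never replace an RBH result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._util import ConfigError, InputError, round_half_up
from .alignment import (
    DEFAULT_GAP_EXTEND,
    DEFAULT_GAP_OPEN,
    DEFAULT_MATRIX,
    GAPPED_K,
    GAPPED_LAMBDA,
    AlignmentHit,
    ProteinEntry,
    local_align,
    raw_local_score,
    significance,
)

#: Relative bit-score tolerance used for "very similar" ties in duplicate
#: mode when the policy does not set one explicitly.
DEFAULT_DUPLICATE_TIE_TOLERANCE = 0.02


@dataclass(frozen=True)
class HitFilterPolicy:
    """Hit acceptance and tie rules for the RBH procedure."""

    max_evalue: float = 1e-6
    min_coverage: float = 0.50
    coverage_mode: str = "either_sequence"  # or "both_sequences"
    tie_tolerance: float = 0.0
    duplicate_mode: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ConfigError("min_coverage must be in [0, 1]")
        if self.tie_tolerance < 0:
            raise ConfigError("tie_tolerance must be >= 0")
        if self.coverage_mode not in ("either_sequence", "both_sequences"):
            raise ConfigError(f"unknown coverage_mode {self.coverage_mode!r}")

    @property
    def effective_tie_tolerance(self) -> float:
        """Exact ties unless duplicate mode activates the relative tolerance."""
        if self.duplicate_mode:
            return self.tie_tolerance or DEFAULT_DUPLICATE_TIE_TOLERANCE
        return self.tie_tolerance


@dataclass(frozen=True)
class OrthologAssignment:
    """A human gene's homologue set in one species."""

    human_gene: str
    species: str
    homologues: tuple[tuple[str, float], ...]  # (gene_id, similarity %)
    provenance: str = "rbh"  # or "override"
    tie: bool = False

    def homologue_ids(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.homologues)


def filter_hits(
    hits: Iterable[AlignmentHit], policy: HitFilterPolicy
) -> list[AlignmentHit]:
    """Apply the E-value and coverage filters.

    Coverage passes when either sequence is covered to ``min_coverage``
    (the default reading of "at least 50 % of any of the protein
    sequences"), or both under ``both_sequences`` mode.
    """
    kept = []
    for h in hits:
        if h.is_empty or h.evalue is None or h.evalue > policy.max_evalue:
            continue
        if policy.coverage_mode == "either_sequence":
            cov_ok = (
                h.query_coverage >= policy.min_coverage
                or h.subject_coverage >= policy.min_coverage
            )
        else:
            cov_ok = (
                h.query_coverage >= policy.min_coverage
                and h.subject_coverage >= policy.min_coverage
            )
        if cov_ok:
            kept.append(h)
    return kept


def best_hit_set(
    hits: Iterable[AlignmentHit], policy: HitFilterPolicy
) -> set[str]:
    """Subjects whose bit score ties the top hit.

    Hits are sorted by descending bit score, then ascending subject id for
    determinism; every subject with bit >= top*(1 - tolerance) is kept
    (exact equality only when the tolerance is zero).
    """
    ranked = sorted(hits, key=lambda h: (-(h.bit_score or 0.0), h.subject_gene))
    if not ranked:
        return set()
    top = ranked[0].bit_score or 0.0
    tol = policy.effective_tie_tolerance
    cutoff = top * (1.0 - tol)
    return {h.subject_gene for h in ranked if (h.bit_score or 0.0) >= cutoff}


def _check_unique(proteome: Sequence[ProteinEntry], label: str) -> None:
    seen: set[str] = set()
    for p in proteome:
        if p.gene_id in seen:
            raise InputError(f"duplicate gene_id {p.gene_id!r} in {label} proteome")
        seen.add(p.gene_id)


def select_canonical(entries: Iterable[ProteinEntry]) -> list[ProteinEntry]:
    """One canonical isoform per gene: longest sequence, then smallest
    accession (then gene id) as the tie-break."""
    by_gene: dict[str, list[ProteinEntry]] = {}
    order: list[str] = []
    for e in entries:
        if e.gene_id not in by_gene:
            order.append(e.gene_id)
        by_gene.setdefault(e.gene_id, []).append(e)
    canonical = []
    for gene in order:
        best = min(
            by_gene[gene],
            key=lambda e: (-len(e.sequence), e.accession, e.gene_id),
        )
        canonical.append(best)
    return canonical


def all_vs_all_hits(
    proteome_a: Sequence[ProteinEntry],
    proteome_b: Sequence[ProteinEntry],
    policy: HitFilterPolicy,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    lam: float = GAPPED_LAMBDA,
    K: float = GAPPED_K,
) -> tuple[dict[str, list[AlignmentHit]], dict[str, list[AlignmentHit]]]:
    """Score every cross-species pair and return filtered directional hits.

    The substitution matrix is symmetric, so each unordered pair is scored
    once; the full traceback (needed for coverage and similarity) is only
    computed for pairs whose E-value already passes the policy threshold in
    at least one direction — other pairs can never survive the filter.

    Returns (hits_by_query_a, hits_by_query_b): for every gene of one
    proteome, its filtered hits into the other proteome.
    """
    db_a = sum(len(p) for p in proteome_a)
    db_b = sum(len(p) for p in proteome_b)
    forward: dict[str, list[AlignmentHit]] = {p.gene_id: [] for p in proteome_a}
    backward: dict[str, list[AlignmentHit]] = {p.gene_id: [] for p in proteome_b}
    for pa in proteome_a:
        for pb in proteome_b:
            score = raw_local_score(
                pa.sequence, pb.sequence, matrix, gap_open, gap_extend
            )
            stub = AlignmentHit(
                query_gene=pa.gene_id,
                subject_gene=pb.gene_id,
                raw_score=score,
                query_length=len(pa),
                subject_length=len(pb),
            )
            fwd = significance(stub, len(pa), db_b, lam, K)
            bwd = significance(stub.swapped(), len(pb), db_a, lam, K)
            if min(fwd.evalue, bwd.evalue) > policy.max_evalue or score <= 0:
                continue
            full = local_align(pa, pb, matrix, gap_open, gap_extend)
            forward[pa.gene_id].append(
                significance(full, len(pa), db_b, lam, K)
            )
            backward[pb.gene_id].append(
                significance(full.swapped(), len(pb), db_a, lam, K)
            )
    for gene in forward:
        forward[gene] = filter_hits(forward[gene], policy)
    for gene in backward:
        backward[gene] = filter_hits(backward[gene], policy)
    return forward, backward


def reciprocal_orthologs(
    proteome_human: Sequence[ProteinEntry],
    proteome_target: Sequence[ProteinEntry],
    policy: HitFilterPolicy | None = None,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[OrthologAssignment]:
    """Reciprocal-best-hit ortholog assignments, human -> target species.

    Both directed searches apply the same filter policy; reciprocity
    requires membership in both best-hit sets. All mutually reciprocal tied
    members form one multi-homologue assignment with ``tie=True``.
    """
    policy = policy or HitFilterPolicy()
    _check_unique(proteome_human, "human")
    _check_unique(proteome_target, "target")
    if not proteome_target:
        return []
    species = proteome_target[0].species
    forward, backward = all_vs_all_hits(
        proteome_human, proteome_target, policy, matrix, gap_open, gap_extend
    )
    best_fwd = {g: best_hit_set(hits, policy) for g, hits in forward.items()}
    best_bwd = {g: best_hit_set(hits, policy) for g, hits in backward.items()}

    assignments = []
    for human in sorted(best_fwd):
        reciprocal = {
            g for g in best_fwd[human] if human in best_bwd.get(g, set())
        }
        if not reciprocal:
            continue
        sim_by_subject = {
            h.subject_gene: round_half_up(100.0 * h.positives_fraction)
            for h in forward[human]
        }
        homologues = tuple(
            (g, sim_by_subject[g]) for g in sorted(reciprocal)
        )
        assignments.append(
            OrthologAssignment(
                human_gene=human,
                species=species,
                homologues=homologues,
                provenance="rbh",
                tie=len(homologues) > 1,
            )
        )
    return assignments


@dataclass(frozen=True)
class Override:
    """A curated functional-homology assignment added post hoc."""

    human_gene: str
    species: str
    gene_id: str
    note: str = ""
    similarity: float = 0.0


def apply_overrides(
    assignments: Sequence[OrthologAssignment],
    overrides: Sequence[Override],
    known_species: Iterable[str] | None = None,
) -> list[OrthologAssignment]:
    """Add curated assignments for genes the sequence filters rejected.

    Overrides are additive: when an RBH assignment already exists for the
    (gene, species) pair the input is returned unchanged for that pair, so
    applying the same override list twice is a no-op.
    """
    if known_species is not None:
        known = set(known_species)
        for ov in overrides:
            if ov.species not in known:
                raise ConfigError(
                    f"override for {ov.human_gene}: unknown species {ov.species!r}"
                )
    existing = {(a.human_gene, a.species) for a in assignments}
    result = list(assignments)
    for ov in overrides:
        if (ov.human_gene, ov.species) in existing:
            continue
        result.append(
            OrthologAssignment(
                human_gene=ov.human_gene,
                species=ov.species,
                homologues=((ov.gene_id, ov.similarity),),
                provenance="override",
                tie=False,
            )
        )
        existing.add((ov.human_gene, ov.species))
    result.sort(key=lambda a: (a.species, a.human_gene))
    return result


def assignments_to_records(
    assignments: Iterable[OrthologAssignment],
) -> list[dict]:
    """Flatten assignments for tabular output (one row per human gene)."""
    rows = []
    for a in assignments:
        rows.append(
            {
                "human_gene": a.human_gene,
                "species": a.species,
                "homologues": ";".join(a.homologue_ids()),
                "similarity": ";".join(
                    f"{s:g}" for _, s in a.homologues
                ),
                "provenance": a.provenance,
                "tie": a.tie,
            }
        )
    return rows
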