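"""Synthetic multi-species proteomes with a known ortholog truth map.

Emulates the evolutionary structure the reciprocal-best-hit method
assumes: an ancestral gene set from which each species independently
retains genes (gene loss), diverges retained copies by per-site residue
substitution, occasionally duplicates a gene (producing near-identical
paralog pairs and hence bit-score ties), and locally shuffles gene order.
No indel process is simulated, so alignments of true orthologs cover the
sequences nearly end to end; indels are an explicit non-goal.

Ancestral residues are drawn from the Robinson-Robinson background
frequencies underlying the BLOSUM statistics, so unrelated sequence pairs
score like random protein matches. A substitution replaces a residue with
a *different* residue sampled from the background distribution.

All randomness is reproducible: one seed per run, with per-species streams
derived from (seed, species name) so adding a species leaves the others'
output unchanged.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._util import ConfigError
from .alignment import ProteinEntry
from .rbh import OrthologAssignment
from .synteny import GenePlacement

#: Robinson & Robinson amino-acid background frequencies (normalized).
_BACKGROUND = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019,
    "Q": 0.043, "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051,
    "L": 0.091, "K": 0.057, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.064,
}
_RESIDUES = np.array(list(_BACKGROUND))
_FREQS = np.array(list(_BACKGROUND.values()))
_FREQS = _FREQS / _FREQS.sum()


@dataclass(frozen=True)
class SpeciesSpec:
    """Evolutionary parameters for one simulated species."""

    name: str
    retention_prob: float = 1.0
    divergence: float = 0.0  # substitutions per site, [0, 1)
    duplication_prob: float = 0.0
    duplicate_divergence: float = 0.0
    order_shuffle_prob: float = 0.0

    def __post_init__(self) -> None:
        for attr in (
            "retention_prob",
            "duplication_prob",
            "duplicate_divergence",
            "order_shuffle_prob",
        ):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{self.name}: {attr}={v} out of [0, 1]")
        if not 0.0 <= self.divergence < 1.0:
            raise ConfigError(f"{self.name}: divergence must be in [0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int
    species: tuple[SpeciesSpec, ...]
    length_range: tuple[int, int] = (80, 200)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        lo, hi = self.length_range
        if lo < 10 or hi < lo:
            raise ConfigError("length_range minimum must be >= 10 and <= maximum")


@dataclass(frozen=True)
class SimulationResult:
    """Proteomes, gene placements and the ancestral truth map."""

    config: SimulationConfig
    ancestor: tuple[ProteinEntry, ...]
    proteomes: Mapping[str, tuple[ProteinEntry, ...]]
    placements: Mapping[str, tuple[GenePlacement, ...]]
    truth: Mapping[str, Mapping[str, tuple[str, ...]]]

    def truth_json(self) -> str:
        return json.dumps(
            {a: {sp: list(v) for sp, v in d.items()} for a, d in self.truth.items()},
            indent=1,
            sort_keys=True,
        )


def _species_rng(seed: int, name: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big") % (2**31))


def _mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return sequence
    seq = np.array(list(sequence))
    hit = rng.random(len(seq)) < rate
    for i in np.nonzero(hit)[0]:
        while True:
            repl = rng.choice(_RESIDUES, p=_FREQS)
            if repl != seq[i]:
                seq[i] = repl
                break
    return "".join(seq)


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate per-species proteomes, placements, and the truth map."""
    root = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    ancestor = []
    for i in range(config.n_genes):
        length = int(root.integers(lo, hi + 1))
        seq = "".join(root.choice(_RESIDUES, size=length, p=_FREQS))
        ancestor.append(
            ProteinEntry(gene_id=f"anc{i:04d}", species="ancestor", sequence=seq)
        )

    proteomes: dict[str, tuple[ProteinEntry, ...]] = {}
    placements: dict[str, tuple[GenePlacement, ...]] = {}
    truth: dict[str, dict[str, tuple[str, ...]]] = {
        a.gene_id: {} for a in ancestor
    }
    for spec in config.species:
        rng = _species_rng(config.seed, spec.name)
        entries: list[ProteinEntry] = []
        for anc in ancestor:
            if rng.random() >= spec.retention_prob:
                truth[anc.gene_id][spec.name] = ()
                continue
            base_id = f"{spec.name}_{anc.gene_id}"
            primary = _mutate(anc.sequence, spec.divergence, rng)
            copies = [(base_id, primary)]
            if rng.random() < spec.duplication_prob:
                dup = _mutate(primary, spec.duplicate_divergence, rng)
                copies.append((base_id + "_dup", dup))
            for gene_id, seq in copies:
                entries.append(
                    ProteinEntry(gene_id=gene_id, species=spec.name, sequence=seq)
                )
            truth[anc.gene_id][spec.name] = tuple(g for g, _ in copies)
        # place genes on one chromosome in ancestral order, then swap each
        # adjacent pair with order_shuffle_prob (single left-to-right pass)
        order = list(range(len(entries)))
        for i in range(len(order) - 1):
            if rng.random() < spec.order_shuffle_prob:
                order[i], order[i + 1] = order[i + 1], order[i]
        placed = []
        for pos, idx in enumerate(order):
            start = 100_000 + pos * 10_000
            placed.append(
                GenePlacement(
                    species=spec.name,
                    gene_id=entries[idx].gene_id,
                    chromosome="chr1",
                    start=start,
                    end=start + 5_000,
                )
            )
        proteomes[spec.name] = tuple(entries)
        placements[spec.name] = tuple(placed)

    return SimulationResult(
        config=config,
        ancestor=tuple(ancestor),
        proteomes=proteomes,
        placements=placements,
        truth=truth,
    )


def _ancestor_index(
    truth: Mapping[str, Mapping[str, Sequence[str]]]
) -> dict[str, str]:
    index = {}
    for anc, per_species in truth.items():
        for genes in per_species.values():
            for g in genes:
                index[g] = anc
    return index


def score_against_truth(
    assignments: Sequence[OrthologAssignment],
    truth: Mapping[str, Mapping[str, Sequence[str]]],
    query_species: str,
    target_species: str,
) -> dict:
    """Precision, recall and tie-accuracy of assignments vs the truth map.

    A (query gene, subject gene) pair is correct when both descend from the
    same ancestral gene. Recall's denominator is every cross pair of
    descendants retained in both species. Tie-accuracy is the fraction of
    ancestral genes with multiple target-species copies whose full copy set
    was returned (as a tie) for at least one query copy. Precision is None
    when nothing was assigned; tie-accuracy is None without duplications.
    """
    ancestor_of = _ancestor_index(truth)
    assigned_pairs = {
        (a.human_gene, hom) for a in assignments for hom in a.homologue_ids()
    }
    correct = {
        (q, s)
        for q, s in assigned_pairs
        if ancestor_of.get(q) is not None and ancestor_of.get(q) == ancestor_of.get(s)
    }
    true_pairs = 0
    dup_ancestors = 0
    dup_recovered = 0
    full_sets = {
        a.human_gene: set(a.homologue_ids()) for a in assignments
    }
    for anc, per_species in truth.items():
        q_desc = list(per_species.get(query_species, ()))
        s_desc = list(per_species.get(target_species, ()))
        if not q_desc or not s_desc:
            continue
        true_pairs += len(q_desc) * len(s_desc)
        if len(s_desc) > 1:
            dup_ancestors += 1
            if any(set(s_desc) <= full_sets.get(q, set()) for q in q_desc):
                dup_recovered += 1
    precision = (
        len(correct) / len(assigned_pairs) if assigned_pairs else None
    )
    recall = len(correct) / true_pairs if true_pairs else None
    tie_accuracy = (
        dup_recovered / dup_ancestors if dup_ancestors else None
    )
    return {
        "precision": precision,
        "recall": recall,
        "tie_accuracy": tie_accuracy,
        "n_assigned_pairs": len(assigned_pairs),
        "n_true_pairs": true_pairs,
    }
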