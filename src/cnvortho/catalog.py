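"""Conservation / mutant-model catalog.

Assembles the per-gene, per-species table of homologues, sequence
similarity and knockout (KO) / knockdown (KD) model availability — the
tabular core of a comparative CNV-region resource — and computes its
summary statistics: per-species conserved counts and percentages, the
cross-species conserved intersection, expression summaries, and model
availability tallies.

Model-availability semantics: "knockout" means a homozygous knockout;
heterozygous phenotypes are carried as free-text notes and never counted.
Absence of data (None) is distinct from an explicit False.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import ConfigError, InputError, percent
from .rbh import OrthologAssignment
from .region import expression_summary  # re-exported: reports use it with tables


@dataclass(frozen=True)
class ModelAvailability:
    """KO/KD availability for one homologue in one species."""

    species: str
    gene_id: str
    knockout: bool | None = None
    knockdown: bool | None = None
    het_phenotype_note: str | None = None
    lethality_note: str | None = None


@dataclass(frozen=True)
class ConservationCell:
    """One gene x species cell: homologue set with similarity and models."""

    homologues: tuple[tuple[str, float], ...]  # (gene_id, similarity %)
    models: Mapping[str, ModelAvailability] = field(default_factory=dict)
    provenance: str = "rbh"

    @property
    def multi(self) -> bool:
        return len(self.homologues) > 1

    def knockout(self) -> bool:
        """Gene-level KO availability: any homologue with a KO model."""
        return any(m.knockout for m in self.models.values() if m.knockout)

    def knockdown(self) -> bool:
        return any(m.knockdown for m in self.models.values() if m.knockdown)


class ConservationTable:
    """Rows: human protein-coding genes in region order; columns: species."""

    def __init__(
        self,
        genes: Sequence[str],
        species: Sequence[str],
        cells: Mapping[tuple[str, str], ConservationCell],
    ):
        self.genes = list(genes)
        self.species = list(species)
        self.cells = dict(cells)
        for (gene, sp) in self.cells:
            if gene not in self.genes:
                raise InputError(f"cell for unknown gene {gene!r}")
            if sp not in self.species:
                raise InputError(f"cell for unknown species {sp!r}")

    def cell(self, gene: str, species: str) -> ConservationCell | None:
        return self.cells.get((gene, species))

    def conserved_genes(self, species: str) -> list[str]:
        if species not in self.species:
            raise InputError(f"unknown species {species!r}")
        return [
            g
            for g in self.genes
            if (g, species) in self.cells and self.cells[(g, species)].homologues
        ]

    # -- construction -----------------------------------------------------

    @classmethod
    def from_assignments(
        cls,
        genes: Sequence[str],
        assignments: Iterable[OrthologAssignment],
        availability: Iterable[ModelAvailability] = (),
    ) -> "ConservationTable":
        avail = {(m.species, m.gene_id): m for m in availability}
        species: list[str] = []
        cells: dict[tuple[str, str], ConservationCell] = {}
        for a in assignments:
            if a.species not in species:
                species.append(a.species)
            models = {
                hom: avail.get(
                    (a.species, hom), ModelAvailability(a.species, hom)
                )
                for hom in a.homologue_ids()
            }
            cells[(a.human_gene, a.species)] = ConservationCell(
                homologues=a.homologues,
                models=models,
                provenance=a.provenance,
            )
        return cls(genes, sorted(species), cells)

    @classmethod
    def from_tsv(
        cls, path: str | Path, genes: Sequence[str] | None = None
    ) -> "ConservationTable":
        """Read the long-form dialect: one row per homologue copy with
        columns human_gene, species, homologue, similarity, model,
        provenance. ``model`` is KO, KD, "KO,KD" or "-" (none available)."""
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        required = ["human_gene", "species", "homologue", "similarity", "model"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise InputError(f"conservation table missing columns: {missing}")
        if genes is None:
            genes = list(dict.fromkeys(df["human_gene"]))
        species = sorted(df["species"].unique())
        grouped: dict[tuple[str, str], list[pd.Series]] = {}
        for _, row in df.iterrows():
            grouped.setdefault((row["human_gene"], row["species"]), []).append(row)
        cells = {}
        for key, rows in grouped.items():
            homologues = []
            models = {}
            provenance = "rbh"
            for row in rows:
                hom = str(row["homologue"])
                homologues.append((hom, float(row["similarity"])))
                code = str(row["model"]).strip()
                models[hom] = ModelAvailability(
                    species=key[1],
                    gene_id=hom,
                    knockout="KO" in code,
                    knockdown="KD" in code,
                )
                if str(row.get("provenance", "rbh")) == "override":
                    provenance = "override"
            cells[key] = ConservationCell(
                homologues=tuple(homologues),
                models=models,
                provenance=provenance,
            )
        return cls(list(genes), species, cells)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in self.genes:
            for sp in self.species:
                cell = self.cells.get((gene, sp))
                if cell is None:
                    continue
                for hom, sim in cell.homologues:
                    m = cell.models.get(hom)
                    code = "-"
                    if m is not None and (m.knockout or m.knockdown):
                        code = ",".join(
                            tag
                            for tag, on in (("KO", m.knockout), ("KD", m.knockdown))
                            if on
                        )
                    rows.append(
                        {
                            "human_gene": gene,
                            "species": sp,
                            "homologue": hom,
                            "similarity": sim,
                            "model": code,
                            "provenance": cell.provenance,
                        }
                    )
        return pd.DataFrame(
            rows,
            columns=[
                "human_gene",
                "species",
                "homologue",
                "similarity",
                "model",
                "provenance",
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ConservationSummary:
    """Per-species conservation counts and the cross-species intersection."""

    n_genes: int
    counts: Mapping[str, int]
    percentages: Mapping[str, float]
    intersection: tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "n_protein_coding": self.n_genes,
            "conserved_counts": dict(self.counts),
            "conserved_percentages": dict(self.percentages),
            "intersection": list(self.intersection),
            "intersection_size": len(self.intersection),
        }


def summarize_conservation(table: ConservationTable) -> ConservationSummary:
    """Conserved counts and half-up one-decimal percentages per species."""
    n = len(table.genes)
    counts = {sp: len(table.conserved_genes(sp)) for sp in table.species}
    percentages = {sp: percent(c, n) for sp, c in counts.items()}
    intersection = (
        intersect_species(table, table.species) if table.species else []
    )
    return ConservationSummary(
        n_genes=n,
        counts=counts,
        percentages=percentages,
        intersection=tuple(intersection),
    )


def intersect_species(
    table: ConservationTable, species: Sequence[str]
) -> list[str]:
    """Genes conserved in every listed species, in region positional order."""
    conserved_sets = [set(table.conserved_genes(sp)) for sp in species]
    if not conserved_sets:
        return []
    common = set.intersection(*conserved_sets)
    return [g for g in table.genes if g in common]


def summarize_models(
    table: ConservationTable,
    species: str,
    denominator_policy: str = "all_conserved",
) -> dict:
    """KO/KD availability tallies over one species' conserved genes.

    ``exclude_multi_homologue`` drops genes whose homologue set has more
    than one member (the convention for duplicated genomes, where it is
    unclear which copy a mutant of interest should target). The four
    categories partition the denominator.
    """
    if denominator_policy not in ("all_conserved", "exclude_multi_homologue"):
        raise ConfigError(f"unknown denominator policy {denominator_policy!r}")
    genes = table.conserved_genes(species)
    if denominator_policy == "exclude_multi_homologue":
        genes = [g for g in genes if not table.cells[(g, species)].multi]
    ko_only = kd_only = both = neither = 0
    for g in genes:
        cell = table.cells[(g, species)]
        ko, kd = cell.knockout(), cell.knockdown()
        if ko and kd:
            both += 1
        elif ko:
            ko_only += 1
        elif kd:
            kd_only += 1
        else:
            neither += 1
    denominator = len(genes)
    tallies = {
        "species": species,
        "denominator_policy": denominator_policy,
        "denominator": denominator,
        "ko_only": ko_only,
        "kd_only": kd_only,
        "both": both,
        "neither": neither,
        "knockout_any": ko_only + both,
        "knockdown_any": kd_only + both,
    }
    for key in ("ko_only", "kd_only", "both", "neither", "knockout_any", "knockdown_any"):
        tallies[f"{key}_pct"] = percent(tallies[key], denominator)
    return tallies
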