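"""End-to-end orchestration: region map -> orthologs -> synteny -> catalog.

A run is described by a declarative YAML/dict config (RunConfig). Inputs
can be supplied as files, or omitted to fall back on the packaged
22q11.2 fixtures; proteome FASTAs, when given, switch the ortholog stage
from the transcribed conservation table to a live reciprocal-best-hit
search. Report bundles are plain TSV/JSON and contain no timestamps, so
two runs on identical inputs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import datasets
from ._util import ConfigError, InputError
from .alignment import read_fasta
from .catalog import (
    ConservationTable,
    expression_summary,
    summarize_conservation,
    summarize_models,
)
from .rbh import (
    HitFilterPolicy,
    Override,
    apply_overrides,
    reciprocal_orthologs,
    OrthologAssignment,
)
from .region import (
    GenomicInterval,
    RegionGeneMap,
    build_region_map,
    read_annotation_tsv,
    subset_proximal,
    write_region_map_tsv,
)
from .synteny import (
    DEFAULT_MAX_GAP,
    GenePlacement,
    chromosome_span,
    clusters_to_frame,
    find_clusters,
    read_placements_tsv,
)


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative description of one end-to-end run."""

    region: GenomicInterval = datasets.REGION_22Q11
    proximal: GenomicInterval | None = datasets.PROXIMAL_22Q11
    annotation: str | None = None  # TSV path; None -> packaged fixture
    conservation_table: str | None = None
    placements: str | None = None
    human_fasta: str | None = None
    species_fastas: Mapping[str, str] = field(default_factory=dict)
    policy: HitFilterPolicy = field(default_factory=HitFilterPolicy)
    duplicate_mode_species: tuple[str, ...] = ()
    overrides: tuple[Override, ...] = ()
    max_gap: int = DEFAULT_MAX_GAP
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: Mapping, base: Path | None = None) -> "RunConfig":
        def resolve(p):
            if p is None:
                return None
            p = Path(p)
            if base is not None and not p.is_absolute():
                p = base / p
            return str(p)

        policy_kwargs = dict(raw.get("filter", {}))
        if "max_evalue" in policy_kwargs:
            policy_kwargs["max_evalue"] = float(policy_kwargs["max_evalue"])
        overrides = tuple(
            Override(
                human_gene=o["human_gene"],
                species=o["species"],
                gene_id=o["gene_id"],
                note=o.get("note", ""),
                similarity=float(o.get("similarity", 0.0)),
            )
            for o in raw.get("overrides", [])
        )
        species_fastas = {
            name: resolve(path)
            for name, path in (raw.get("species_fastas") or {}).items()
        }
        return cls(
            region=GenomicInterval.from_string(raw["region"])
            if "region" in raw
            else datasets.REGION_22Q11,
            proximal=GenomicInterval.from_string(raw["proximal"])
            if "proximal" in raw
            else datasets.PROXIMAL_22Q11,
            annotation=resolve(raw.get("annotation")),
            conservation_table=resolve(raw.get("conservation_table")),
            placements=resolve(raw.get("placements")),
            human_fasta=resolve(raw.get("human_fasta")),
            species_fastas=species_fastas,
            policy=HitFilterPolicy(**policy_kwargs),
            duplicate_mode_species=tuple(raw.get("duplicate_mode_species", ())),
            overrides=overrides,
            max_gap=int(raw.get("max_gap", DEFAULT_MAX_GAP)),
            seed=int(raw.get("seed", 0)),
        )


def _check_exists(path: str | None, stage: str) -> None:
    if path is not None and not Path(path).exists():
        raise StageError(stage, f"input file not found: {path}")


def summarize_run(
    region_map: RegionGeneMap,
    proximal: GenomicInterval | None,
    table: ConservationTable,
    placements: Mapping[str, Sequence[GenePlacement]] | None = None,
    max_gap: int = DEFAULT_MAX_GAP,
) -> dict:
    """The summary-report dict shared by the CLI and the fixture analysis."""
    report: dict = {
        "region": str(region_map.region),
        "census": dict(region_map.census),
        "n_genes": len(region_map),
    }
    coding = region_map.protein_coding()
    n_coding = len(coding)
    for field_name in ("brain_expressed", "decreased_in_deletion"):
        count, pct = expression_summary(region_map, field_name)
        report[field_name] = {
            "count": count,
            "denominator": n_coding,
            "percent": pct,
        }
    if proximal is not None:
        prox_map = subset_proximal(region_map, proximal)
        count, pct = expression_summary(prox_map, "brain_expressed")
        report["proximal"] = {
            "interval": str(proximal),
            "n_genes": len(prox_map),
            "census": dict(prox_map.census),
            "brain_expressed": {
                "count": count,
                "denominator": len(prox_map.protein_coding()),
                "percent": pct,
            },
        }
    summary = summarize_conservation(table)
    report["conservation"] = summary.as_dict()
    report["models"] = {}
    for sp in table.species:
        policy = (
            "exclude_multi_homologue" if sp == "zebrafish" else "all_conserved"
        )
        report["models"][sp] = summarize_models(table, sp, policy)
    if placements is not None and "human" in placements:
        report["synteny"] = {}
        for sp in table.species:
            if sp not in placements:
                continue
            assignments = _table_to_assignments(table, sp)
            clusters = find_clusters(
                assignments, placements["human"], placements[sp], max_gap
            )
            n_chrom, tallies = chromosome_span(assignments, placements[sp])
            report["synteny"][sp] = {
                "n_chromosomes": n_chrom,
                "per_chromosome": tallies,
                "clusters": [
                    {
                        "chromosome": c.target_chromosome,
                        "human_genes": list(c.human_genes),
                        "collinear": c.collinear,
                    }
                    for c in clusters
                ],
            }
    return report


def _table_to_assignments(
    table: ConservationTable, species: str
) -> list[OrthologAssignment]:
    out = []
    for gene in table.conserved_genes(species):
        cell = table.cells[(gene, species)]
        out.append(
            OrthologAssignment(
                human_gene=gene,
                species=species,
                homologues=cell.homologues,
                provenance=cell.provenance,
                tie=cell.multi,
            )
        )
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages and write the report bundle into ``out_dir``.

    Returns the summary report dict (also written as summary.json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- region map -------------------------------------------------------
    try:
        _check_exists(config.annotation, "region_map")
        annotation = (
            read_annotation_tsv(config.annotation)
            if config.annotation
            else datasets.load_region_annotation()
        )
        region_map = build_region_map(annotation, config.region)
    except (InputError, ConfigError) as exc:
        raise StageError("region_map", str(exc)) from exc
    write_region_map_tsv(region_map, out / "region_map.tsv")
    (out / "census.json").write_text(
        json.dumps(dict(region_map.census), indent=1, sort_keys=True) + "\n"
    )

    # --- orthologs --------------------------------------------------------
    try:
        if config.species_fastas:
            _check_exists(config.human_fasta, "orthologs")
            if config.human_fasta is None:
                raise StageError("orthologs", "species FASTAs given without human_fasta")
            human = read_fasta(config.human_fasta, species="human")
            assignments: list[OrthologAssignment] = []
            for sp, fasta in sorted(config.species_fastas.items()):
                _check_exists(fasta, "orthologs")
                target = read_fasta(fasta, species=sp)
                policy = config.policy
                if sp in config.duplicate_mode_species:
                    policy = HitFilterPolicy(
                        max_evalue=policy.max_evalue,
                        min_coverage=policy.min_coverage,
                        coverage_mode=policy.coverage_mode,
                        tie_tolerance=policy.tie_tolerance,
                        duplicate_mode=True,
                    )
                assignments.extend(
                    reciprocal_orthologs(human, target, policy)
                )
            assignments = apply_overrides(
                assignments,
                config.overrides,
                known_species=set(config.species_fastas),
            )
            # rows in region positional order when the query proteome maps
            # onto the region's coding genes; FASTA order otherwise
            human_ids = [p.gene_id for p in human]
            genes = [
                g.gene_id
                for g in region_map.protein_coding()
                if g.gene_id in set(human_ids)
            ] or human_ids
            table = ConservationTable.from_assignments(genes, assignments)
        else:
            _check_exists(config.conservation_table, "orthologs")
            if config.conservation_table:
                genes = [g.gene_id for g in region_map.protein_coding()]
                table = ConservationTable.from_tsv(
                    config.conservation_table, genes=genes
                )
            else:
                table = datasets.load_conservation_table()
    except (InputError, ConfigError) as exc:
        raise StageError("orthologs", str(exc)) from exc
    table.to_tsv(out / "orthologs.tsv")

    # --- synteny ----------------------------------------------------------
    placements: dict[str, list[GenePlacement]] | None
    try:
        if config.placements:
            _check_exists(config.placements, "synteny")
            placements = {}
            for p in read_placements_tsv(config.placements):
                placements.setdefault(p.species, []).append(p)
            placements.setdefault(
                "human",
                [
                    GenePlacement(
                        species="human",
                        gene_id=g.gene_id,
                        chromosome=g.interval.chromosome,
                        start=g.interval.start,
                        end=g.interval.end,
                    )
                    for g in region_map
                ],
            )
        elif not config.species_fastas and not config.conservation_table:
            placements = datasets.load_placements()
        else:
            placements = None
        if placements is not None:
            frames = []
            for sp in table.species:
                if sp in placements:
                    clusters = find_clusters(
                        _table_to_assignments(table, sp),
                        placements["human"],
                        placements[sp],
                        config.max_gap,
                    )
                    frames.append(clusters_to_frame(clusters))
            if frames:
                import pandas as pd

                pd.concat(frames, ignore_index=True).to_csv(
                    out / "clusters.tsv", sep="\t", index=False
                )
    except (InputError, ConfigError) as exc:
        raise StageError("synteny", str(exc)) from exc

    # --- catalog / summary ------------------------------------------------
    try:
        report = summarize_run(
            region_map, config.proximal, table, placements, config.max_gap
        )
    except (InputError, ConfigError) as exc:
        raise StageError("catalog", str(exc)) from exc
    (out / "summary.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n"
    )
    return report
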