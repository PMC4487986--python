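"""Packaged 22q11.2 deletion-region fixtures.

The shipped tables transcribe the published comparative map of the typical
~2.5-Mb 22q11.2 deletion: the 90-gene region map with biotypes and
expression flags, the gene x species conservation/model-availability
table, and homologue genome placements. Gene coordinates and the names of
non-protein-coding entries are synthesized within the published breakpoint
interval (real coordinates are not part of the source tables); gene
counts, order constraints, homologue names, similarities and model codes
are transcribed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .catalog import ConservationTable
from .region import (
    GenomicInterval,
    RegionGeneMap,
    build_region_map,
    read_annotation_tsv,
)
from .rbh import Override
from .synteny import GenePlacement, read_placements_tsv

#: Array mean breakpoints of the typical deletion.
REGION_22Q11 = GenomicInterval("chr22", 18_820_303, 21_489_474)

#: The nested proximal (~1.5 Mb, LCR A-B) deletion. The distal breakpoint
#: is not published at base resolution; the fixture places it between the
#: 55th and 56th transcribed genes.
PROXIMAL_22Q11 = GenomicInterval("chr22", 18_820_303, 20_310_000)

SPECIES = ("worm", "fly", "zebrafish", "mouse")

#: Curated functional-homology overrides: MED15/mdt-15 fails the 50 %
#: coverage filter but is an experimentally confirmed functional homologue.
OVERRIDES = (
    Override(
        human_gene="MED15",
        species="worm",
        gene_id="mdt-15",
        note="confirmed functional homology; coverage < 50 %",
        similarity=26.0,
    ),
)


def _data_path(name: str):
    return resources.files("cnvortho.data") / name


def load_region_annotation():
    """The 90-gene region annotation (list of GeneAnnotation)."""
    with resources.as_file(_data_path("region_genes.tsv")) as path:
        return read_annotation_tsv(path)


def load_region_map() -> RegionGeneMap:
    return build_region_map(load_region_annotation(), REGION_22Q11)


def load_conservation_table() -> ConservationTable:
    """The conservation / mutant-model table over the 46 coding genes."""
    region_map = load_region_map()
    genes = [g.gene_id for g in region_map.protein_coding()]
    with resources.as_file(_data_path("conservation.tsv")) as path:
        return ConservationTable.from_tsv(path, genes=genes)


def load_placements() -> dict[str, list[GenePlacement]]:
    """Homologue placements per species, plus human region placements."""
    with resources.as_file(_data_path("placements.tsv")) as path:
        placements = read_placements_tsv(path)
    by_species: dict[str, list[GenePlacement]] = {}
    for p in placements:
        by_species.setdefault(p.species, []).append(p)
    by_species["human"] = [
        GenePlacement(
            species="human",
            gene_id=g.gene_id,
            chromosome=g.interval.chromosome,
            start=g.interval.start,
            end=g.interval.end,
        )
        for g in load_region_map()
    ]
    return by_species


def load_mirna_conservation() -> pd.DataFrame:
    """Curated miRNA conservation flags (a recorded fact, not computed)."""
    with resources.as_file(_data_path("mirna_conservation.tsv")) as path:
        return pd.read_csv(path, sep="\t", keep_default_na=False)
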