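"""Deletion-region gene maps.

Builds the gene map of a copy-number-variant interval from a genome
annotation table: which genes the deletion overlaps, their biotypes, brain
expression, and the nested proximal subset. Coordinates are 1-based, fully
closed (NCBI convention); a gene belongs to the region when it shares at
least one base with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import InputError, ConfigError, percent

BIOTYPES = ("protein_coding", "pseudogene", "ncRNA", "miRNA", "read_through")

#: mRNA signal level at or above which a gene counts as brain-expressed.
BRAIN_SIGNAL_THRESHOLD = 6.0


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, fully closed genomic interval."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise InputError("interval chromosome must be non-empty")
        if self.start > self.end:
            raise InputError(
                f"interval start {self.start} > end {self.end} on {self.chromosome}"
            )
        if self.start < 1:
            raise InputError(f"interval start {self.start} must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.start
            and other.end <= self.end
        )

    @classmethod
    def from_string(cls, text: str) -> "GenomicInterval":
        """Parse "chr22:18820303-21489474" (commas in numbers tolerated)."""
        try:
            chrom, span = text.split(":")
            lo, hi = span.replace(",", "").split("-")
            return cls(chrom, int(lo), int(hi))
        except (ValueError, AttributeError) as exc:
            raise InputError(f"cannot parse interval {text!r}") from exc

    def __str__(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene's placement, biotype and expression flags.

    ``brain_signal`` is the maximum mRNA signal observed in any brain
    region/timepoint; ``brain_expressed`` may be supplied directly when no
    signal is available (e.g. from a secondary expression database), and is
    otherwise derived as ``signal >= threshold``. ``decreased_in_deletion``
    records experimentally demonstrated reduced expression in deletion
    carriers; None means unstudied, which is distinct from False.
    """

    gene_id: str
    symbol: str
    interval: GenomicInterval
    strand: str = "+"
    biotype: str = "protein_coding"
    brain_signal: float | None = None
    brain_expressed: bool | None = None
    decreased_in_deletion: bool | None = None

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise InputError(
                f"gene {self.gene_id}: unknown biotype {self.biotype!r}"
            )
        if self.strand not in ("+", "-"):
            raise InputError(f"gene {self.gene_id}: strand must be + or -")
        if self.brain_signal is not None and self.brain_signal < 0:
            raise InputError(
                f"gene {self.gene_id}: negative brain signal {self.brain_signal}"
            )


@dataclass(frozen=True)
class RegionGeneMap:
    """Genes overlapping a region, sorted by start position."""

    region: GenomicInterval
    genes: tuple[GeneAnnotation, ...]
    census: Mapping[str, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.census is None:
            counts = {b: 0 for b in BIOTYPES}
            for g in self.genes:
                counts[g.biotype] += 1
            object.__setattr__(self, "census", counts)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def protein_coding(self) -> tuple[GeneAnnotation, ...]:
        return tuple(g for g in self.genes if g.biotype == "protein_coding")

    def gene(self, gene_id: str) -> GeneAnnotation:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def build_region_map(
    annotation: Iterable[GeneAnnotation], region: GenomicInterval
) -> RegionGeneMap:
    """Select the genes overlapping ``region`` by at least one base.

    Genes are returned sorted by start position (ties broken by gene id so
    the output is deterministic for any input ordering).
    """
    selected = [g for g in annotation if g.interval.overlaps(region)]
    selected.sort(key=lambda g: (g.interval.start, g.gene_id))
    return RegionGeneMap(region=region, genes=tuple(selected))


def census_biotypes(region_map: RegionGeneMap) -> dict[str, int]:
    """Counts per biotype; always contains all five biotype keys."""
    return dict(region_map.census)


def annotate_expression(
    region_map: RegionGeneMap,
    signals: Mapping[str, float | Sequence[float]],
    threshold: float = BRAIN_SIGNAL_THRESHOLD,
) -> RegionGeneMap:
    """Set ``brain_expressed`` from mRNA signal tables.

    ``signals`` maps gene id to a signal value or a sequence of values (one
    per brain region/timepoint); a gene is expressed when any value reaches
    ``threshold`` (inclusive). Genes absent from ``signals`` keep their
    pre-existing flag, which may have been supplied directly.
    """
    updated = []
    for g in region_map.genes:
        if g.gene_id in signals:
            raw = signals[g.gene_id]
            values = [raw] if isinstance(raw, (int, float)) else list(raw)
            for v in values:
                if v < 0:
                    raise InputError(
                        f"gene {g.gene_id}: negative brain signal {v}"
                    )
            best = max(values)
            g = replace(g, brain_signal=best, brain_expressed=best >= threshold)
        updated.append(g)
    return RegionGeneMap(region=region_map.region, genes=tuple(updated))


def subset_proximal(
    region_map: RegionGeneMap, proximal: GenomicInterval
) -> RegionGeneMap:
    """Restrict the map to a nested (e.g. proximal low-copy-repeat) interval."""
    if not region_map.region.contains(proximal):
        raise InputError(
            f"proximal interval {proximal} is not contained in region "
            f"{region_map.region}"
        )
    return build_region_map(region_map.genes, proximal)


def expression_summary(
    region_map: RegionGeneMap, field_name: str = "brain_expressed"
) -> tuple[int, float]:
    """Count protein-coding genes with a true expression flag.

    Returns ``(count, percentage)`` where the percentage is over all
    protein-coding genes in the map, rounded half-up to one decimal. Use on
    a proximal submap for proximal-scope summaries.
    """
    if field_name not in ("brain_expressed", "decreased_in_deletion"):
        raise ConfigError(f"unknown expression field {field_name!r}")
    coding = region_map.protein_coding()
    count = sum(1 for g in coding if getattr(g, field_name) is True)
    return count, percent(count, len(coding))


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end", "strand", "biotype"]
_OPTIONAL = ["brain_signal", "brain_expressed", "decreased_in_deletion"]


def _parse_flag(value) -> bool | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise InputError(f"cannot parse boolean flag {value!r}")


def _row_to_gene(row: pd.Series) -> GeneAnnotation:
    try:
        interval = GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"]))
    except (InputError, ValueError) as exc:
        raise InputError(f"gene {row['gene_id']}: malformed interval") from exc
    signal = row.get("brain_signal")
    if signal is not None and pd.isna(signal):
        signal = None
    return GeneAnnotation(
        gene_id=str(row["gene_id"]),
        symbol=str(row["symbol"]),
        interval=interval,
        strand=str(row["strand"]),
        biotype=str(row["biotype"]),
        brain_signal=float(signal) if signal is not None else None,
        brain_expressed=_parse_flag(row.get("brain_expressed")),
        decreased_in_deletion=_parse_flag(row.get("decreased_in_deletion")),
    )


def read_annotation_tsv(path: str | Path) -> list[GeneAnnotation]:
    """Read the native annotation dialect (1-based closed coordinates)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"annotation table missing columns: {missing}")
    return [_row_to_gene(row) for _, row in df.iterrows()]


def read_annotation_bed6(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED6 file (0-based, half-open), converting to 1-based closed.

    BED carries no biotype; every record is loaded as protein_coding and the
    name column doubles as gene id and symbol.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    genes = []
    for _, row in df.iterrows():
        interval = GenomicInterval(str(row["chrom"]), int(row["start"]) + 1, int(row["end"]))
        genes.append(
            GeneAnnotation(
                gene_id=str(row["name"]),
                symbol=str(row["name"]),
                interval=interval,
                strand=str(row["strand"]),
            )
        )
    return genes


def region_map_to_frame(region_map: RegionGeneMap) -> pd.DataFrame:
    rows = []
    for g in region_map.genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "symbol": g.symbol,
                "chrom": g.interval.chromosome,
                "start": g.interval.start,
                "end": g.interval.end,
                "strand": g.strand,
                "biotype": g.biotype,
                "brain_signal": g.brain_signal,
                "brain_expressed": g.brain_expressed,
                "decreased_in_deletion": g.decreased_in_deletion,
            }
        )
    return pd.DataFrame(rows, columns=_COLUMNS + _OPTIONAL)


def write_region_map_tsv(region_map: RegionGeneMap, path: str | Path) -> None:
    region_map_to_frame(region_map).to_csv(path, sep="\t", index=False)
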