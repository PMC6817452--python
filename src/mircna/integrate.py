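"""Integration of differential miRNA expression with recurrent CNA regions.

Two approaches are implemented. First, differentially expressed miRNAs are
mapped by genomic locus into recurrent CNA regions (any-overlap, >= 1 base)
and filtered for direction concordance: copy-number gain with up-regulation,
or loss with down-regulation. Second, predicted target genes are voted
across independent databases (kept when >= k databases agree) and
intersected with the genes inside the CNA regions, yielding the set of genes
potentially hit by both mechanisms and the reduction statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cna import RecurrentRegion, _chrom_sort_key

__all__ = [
    "MiRNALocus",
    "TargetPredictionSet",
    "IntegrationSummary",
    "map_to_regions",
    "concordance_filter",
    "vote_targets",
    "intersect_targets_with_cna_genes",
    "summarize_integration",
    "percent",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MiRNALocus:
    """Genomic location of a miRNA gene (1-based inclusive)."""

    name: str
    chrom: str
    start: int
    stop: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValueError(f"locus start > stop for {self.name}")


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass
class TargetPredictionSet:
    """One database's miRNA -> predicted target-gene mapping."""

    database: str
    targets: dict[str, frozenset[str]]

    @classmethod
    def from_pairs(
        cls, database: str, pairs: Iterable[tuple[str, str]]
    ) -> "TargetPredictionSet":
        mapping: dict[str, set[str]] = {}
        for mirna, gene in pairs:
            mapping.setdefault(mirna.strip(), set()).add(normalize_symbol(gene))
        return cls(database, {m: frozenset(g) for m, g in mapping.items()})


@dataclass
class IntegrationSummary:
    """Counts and percentages tracking the integration funnel."""

    n_de: int
    n_mapped: int
    n_concordant: int
    n_targets_union: int
    n_intersected: int
    pct_mapped: float | None = field(init=False)
    pct_concordant: float | None = field(init=False)
    pct_reduction: float | None = field(init=False)

    def __post_init__(self) -> None:
        if not (self.n_concordant <= self.n_mapped <= self.n_de):
            raise ValueError("need n_concordant <= n_mapped <= n_de")
        if self.n_intersected > self.n_targets_union:
            raise ValueError("intersection cannot exceed the target union")
        self.pct_mapped = percent(self.n_mapped, self.n_de)
        self.pct_concordant = percent(self.n_concordant, self.n_mapped)
        self.pct_reduction = (
            percent(self.n_targets_union - self.n_intersected, self.n_targets_union)
        )

    def to_dict(self) -> dict:
        return {
            "n_de": self.n_de,
            "n_mapped": self.n_mapped,
            "pct_mapped": self.pct_mapped,
            "n_concordant": self.n_concordant,
            "pct_concordant": self.pct_concordant,
            "n_targets_union": self.n_targets_union,
            "n_intersected": self.n_intersected,
            "pct_reduction": self.pct_reduction,
        }


def percent(numerator: int, denominator: int) -> float | None:
    """Percentage to one decimal place; None for a zero denominator."""
    if denominator == 0:
        return None
    return round(100.0 * numerator / denominator, 1)


def map_to_regions(
    de: pd.DataFrame,
    loci: Sequence[MiRNALocus] | Mapping[str, MiRNALocus],
    regions: Sequence[RecurrentRegion],
) -> pd.DataFrame:
    """Map DE miRNAs into recurrent regions by locus overlap.

    ``de`` needs columns ``mirna, log2fc, q``. A miRNA maps iff its locus
    overlaps any region by >= 1 base; with several overlapping regions the
    largest overlap wins (ties: first region in chromosome/start order).
    miRNAs without a locus record, or with a non-overlapping locus, are
    excluded from the output (and logged) but remain part of the DE
    denominator kept by the caller.
    """
    if isinstance(loci, Mapping):
        locus_by_name = dict(loci)
    else:
        locus_by_name = {l.name: l for l in loci}
    ordered_regions = sorted(
        regions, key=lambda r: (_chrom_sort_key(r.chrom), r.start, r.direction)
    )
    rows = []
    for rec in de.itertuples(index=False):
        locus = locus_by_name.get(rec.mirna)
        if locus is None:
            logger.warning("miRNA %s has no locus record; cannot map", rec.mirna)
            continue
        best = None
        best_overlap = 0
        for region in ordered_regions:
            if not region.overlaps(locus.chrom, locus.start, locus.stop):
                continue
            overlap = min(region.stop, locus.stop) - max(region.start, locus.start) + 1
            if overlap > best_overlap:
                best, best_overlap = region, overlap
        if best is None:
            logger.info("miRNA %s maps outside every region", rec.mirna)
            continue
        rows.append(
            {
                "mirna": rec.mirna,
                "chrom": locus.chrom,
                "start": locus.start,
                "stop": locus.stop,
                "log2fc": rec.log2fc,
                "q": rec.q,
                "expression_direction": "up" if rec.log2fc > 0 else "down",
                "cna_direction": best.direction,
                "region_chrom": best.chrom,
                "region_start": best.start,
                "region_stop": best.stop,
                "region_label": best.label,
                "overlap_bp": best_overlap,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna", "chrom", "start", "stop", "log2fc", "q",
            "expression_direction", "cna_direction",
            "region_chrom", "region_start", "region_stop", "region_label",
            "overlap_bp",
        ],
    )


def concordance_filter(mapped: pd.DataFrame) -> pd.DataFrame:
    """Keep direction-concordant entries: gain & up, or loss & down.

    Output is sorted by chromosome then start, mirroring a printed panel
    table ordered by genomic position.
    """
    if mapped.empty:
        return mapped.copy()
    keep = (
        ((mapped["cna_direction"] == "gain") & (mapped["expression_direction"] == "up"))
        | ((mapped["cna_direction"] == "loss") & (mapped["expression_direction"] == "down"))
    )
    panel = mapped.loc[keep].copy()
    panel["_key"] = panel["chrom"].map(_chrom_sort_key)
    panel = panel.sort_values(["_key", "start"]).drop(columns="_key")
    return panel.reset_index(drop=True)


def vote_targets(
    prediction_sets: Sequence[TargetPredictionSet],
    min_databases: int = 2,
) -> dict[str, frozenset[str]]:
    """Retain (miRNA, gene) pairs predicted by >= ``min_databases`` databases."""
    if min_databases < 1:
        raise ValueError("min_databases must be >= 1")
    if min_databases > len(prediction_sets):
        raise ValueError(
            f"min_databases={min_databases} exceeds the {len(prediction_sets)} "
            "prediction sets supplied"
        )
    votes: dict[str, dict[str, int]] = {}
    for pset in prediction_sets:
        for mirna, genes in pset.targets.items():
            tally = votes.setdefault(mirna, {})
            for gene in genes:
                tally[gene] = tally.get(gene, 0) + 1
    return {
        mirna: frozenset(g for g, n in tally.items() if n >= min_databases)
        for mirna, tally in votes.items()
        if any(n >= min_databases for n in tally.values())
    }


def intersect_targets_with_cna_genes(
    voted: Mapping[str, frozenset[str]],
    region_genes: Iterable[Iterable[str]] | Iterable[str],
) -> tuple[frozenset[str], dict]:
    """Intersect the voted-target union with the union of CNA-region genes.

    ``region_genes`` may be per-region gene lists or a flat iterable of
    symbols. Returns the common gene set and a dict with the union count,
    intersection count and percent reduction (None when the union is empty).
    """
    union_targets: set[str] = set()
    for genes in voted.values():
        union_targets |= set(genes)
    flat: set[str] = set()
    for item in region_genes:
        if isinstance(item, str):
            flat.add(normalize_symbol(item))
        else:
            flat.update(normalize_symbol(g) for g in item)
    common = frozenset(union_targets & flat)
    n_union = len(union_targets)
    summary = {
        "n_targets_union": n_union,
        "n_intersected": len(common),
        "pct_reduction": percent(n_union - len(common), n_union),
    }
    return common, summary


def summarize_integration(
    n_de: int,
    n_mapped: int,
    n_concordant: int,
    n_targets_union: int,
    n_intersected: int,
) -> IntegrationSummary:
    """Assemble the funnel summary with percentages to one decimal place."""
    return IntegrationSummary(
        n_de=n_de,
        n_mapped=n_mapped,
        n_concordant=n_concordant,
        n_targets_union=n_targets_union,
        n_intersected=n_intersected,
    )
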