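"""Bundled reference-study tables and headline counts.

The package ships the printed summary tables of the reference breast-cancer
study it re-implements: the recurrent CNA regions of the TNBC and non-TNBC
groups (with per-region case counts and gene tallies) and the 17-miRNA
concordance panel (loci, CNA/expression directions, log2 fold changes).
These serve as ready-made inputs for the desk-scale worked examples and the
reproduction script; cohort-level raw data was never deposited and is
emulated by :mod:`mircna.simulate`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cna import RecurrentRegion

__all__ = [
    "tnbc_regions",
    "non_tnbc_regions",
    "panel_table",
    "panel_loci",
    "STUDY_COUNTS",
]

#: headline counts printed by the reference study, used as inputs to the
#: summary arithmetic (call burden, integration funnel percentages).
STUDY_COUNTS = {
    "n_calls_tnbc": 292,
    "n_calls_non_tnbc": 204,
    "n_flagged_tnbc": 16,  # TNBC cases with >= 1 significant segment (of 25)
    "n_flagged_non_tnbc": 14,  # non-TNBC cases with >= 1 significant segment (of 16)
    "n_de_mirnas": 163,  # differentially expressed miRNAs (p <= 0.05, FDR <= 0.25)
    "n_de_up": 87,  # of which up-regulated in TNBC
    "n_mapped_mirnas": 45,  # DE miRNAs located inside recurrent CNA regions
    "n_concordant_mirnas": 17,  # direction-concordant panel
    "n_voted_targets": 10675,  # >= 2-of-3 database target union over the panel
    "n_common_genes": 2098,  # targets also inside the CNA regions
}


def _read_data(name: str) -> pd.DataFrame:
    with resources.files("mircna.data").joinpath(name).open("r") as handle:
        return pd.read_csv(handle, sep="\t")


def _to_regions(frame: pd.DataFrame) -> list[RecurrentRegion]:
    return [
        RecurrentRegion(
            chrom=row.chrom,
            start=int(row.start),
            stop=int(row.stop),
            direction=row.direction,
            n_cases=int(row.n_cases),
            denominator=int(row.denominator),
            frequency=int(row.n_cases) / int(row.denominator),
            label=row.cytoband,
            n_genes=int(row.n_genes),
        )
        for row in frame.itertuples(index=False)
    ]


def tnbc_regions(as_frame: bool = False):
    """The 15 recurrent CNA regions of the TNBC group (denominator 16)."""
    frame = _read_data("tnbc_regions.tsv")
    return frame if as_frame else _to_regions(frame)


def non_tnbc_regions(as_frame: bool = False):
    """The 7 recurrent CNA regions of the non-TNBC group (denominator 14)."""
    frame = _read_data("non_tnbc_regions.tsv")
    return frame if as_frame else _to_regions(frame)


def panel_table() -> pd.DataFrame:
    """The 17-miRNA concordance panel: loci, directions, log2FC, adjusted p.

    One row's adjusted p was printed only as an upper bound (< 0.05) and is
    stored as 0.05; downstream logic uses the log2FC sign, not this value.
    """
    return _read_data("mirna_panel.tsv")


def panel_loci() -> pd.DataFrame:
    """Panel miRNA loci as a ``name, chrom, start, stop`` table.

    Chromosome labels are derived from the cytoband (e.g. ``1q32.1`` ->
    ``chr1``).
    """
    table = panel_table()
    chrom = table["cytoband"].str.extract(r"^(\d+|X|Y)")[0].map("chr{}".format)
    return pd.DataFrame(
        {
            "name": table["mirna"],
            "chrom": chrom,
            "start": table["start"],
            "stop": table["stop"],
        }
    )
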