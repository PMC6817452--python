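"""Readers and writers for the pipeline's plain-text formats.

TSV files are tab-separated with a header row, UTF-8, '.' decimal. Internal
coordinates are 1-based inclusive; BED input (0-based half-open) is
converted on read and back on write. Chromosome labels normalize to the
``chrN`` form.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cna import RecurrentRegion, SegmentCall
from .integrate import TargetPredictionSet

__all__ = [
    "ParseError",
    "normalize_chrom",
    "read_probe_table",
    "write_probe_table",
    "read_counts_csv",
    "write_counts_csv",
    "read_clinical_csv",
    "write_clinical_csv",
    "read_interval_report",
    "write_segments",
    "read_regions",
    "write_regions",
    "read_bed",
    "write_bed",
    "read_gmt",
    "write_gmt",
    "read_target_predictions",
    "read_de_table",
    "write_de_table",
    "write_json",
    "read_json",
]


class ParseError(ValueError):
    """Malformed input file; the message names the file, column or line."""


def normalize_chrom(label: str) -> str:
    name = str(label).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if not name:
        raise ParseError("empty chromosome label")
    return "chr" + name.upper() if name.upper() in ("X", "Y") else "chr" + name


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")


# --- probe table -----------------------------------------------------------


def read_probe_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, ["sample", "chrom", "position", "log2_ratio"], path)
    frame["chrom"] = frame["chrom"].map(normalize_chrom)
    return frame


def write_probe_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


# --- counts / clinical -----------------------------------------------------


def read_counts_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col=0)
    if "probe_class" not in frame.columns:
        raise ParseError(f"{path}: missing required column(s) ['probe_class']")
    return frame


def write_counts_csv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path)


def read_clinical_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, ["sample", "group"], path)
    frame["sample"] = frame["sample"].astype(str)
    return frame


def write_clinical_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def labels_from_clinical(frame: pd.DataFrame) -> dict[str, str]:
    return dict(zip(frame["sample"], frame["group"]))


# --- segments and regions --------------------------------------------------

_REPORT_REQUIRED = ["sample", "chrom", "start", "stop", "direction"]


def read_interval_report(path) -> list[SegmentCall]:
    """Parse a pre-called aberration interval report TSV into segment calls.

    Required columns: sample, chrom, start, stop, direction; optional:
    cytoband, mean_log2, n_probes, genes. Rows with start > stop raise a
    :class:`ParseError` naming the line.
    """
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, _REPORT_REQUIRED, path)
    calls = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        start, stop = int(row.start), int(row.stop)
        if start > stop:
            raise ParseError(f"{path}: line {i}: start {start} > stop {stop}")
        mean_log2 = getattr(row, "mean_log2", 0.0)
        n_probes = getattr(row, "n_probes", 0)
        calls.append(
            SegmentCall(
                sample=str(row.sample),
                chrom=normalize_chrom(row.chrom),
                start=start,
                stop=stop,
                direction=str(row.direction),
                mean_log2=0.0 if pd.isna(mean_log2) else float(mean_log2),
                n_probes=0 if pd.isna(n_probes) else int(n_probes),
            )
        )
    return calls


def write_segments(calls: Iterable[SegmentCall], path) -> None:
    frame = pd.DataFrame(
        [
            {"sample": c.sample, "chrom": c.chrom, "start": c.start,
             "stop": c.stop, "direction": c.direction,
             "mean_log2": c.mean_log2, "n_probes": c.n_probes}
            for c in calls
        ],
        columns=["sample", "chrom", "start", "stop", "direction",
                 "mean_log2", "n_probes"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_segments(path) -> list[SegmentCall]:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(
        frame, ["sample", "chrom", "start", "stop", "direction",
                "mean_log2", "n_probes"], path,
    )
    return [
        SegmentCall(str(r.sample), normalize_chrom(r.chrom), int(r.start),
                    int(r.stop), str(r.direction), float(r.mean_log2),
                    int(r.n_probes))
        for r in frame.itertuples(index=False)
    ]


def write_regions(regions: Iterable[RecurrentRegion], path) -> None:
    frame = pd.DataFrame(
        [
            {"chrom": r.chrom, "cytoband": r.label or "", "start": r.start,
             "stop": r.stop, "direction": r.direction, "n_cases": r.n_cases,
             "denominator": r.denominator,
             "frequency": round(r.frequency, 6),
             "n_genes": "" if r.n_genes is None else r.n_genes}
            for r in regions
        ],
        columns=["chrom", "cytoband", "start", "stop", "direction",
                 "n_cases", "denominator", "frequency", "n_genes"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_regions(path) -> list[RecurrentRegion]:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(
        frame, ["chrom", "start", "stop", "direction", "n_cases",
                "denominator"], path,
    )
    regions = []
    for r in frame.itertuples(index=False):
        n_genes = getattr(r, "n_genes", None)
        n_genes = None if pd.isna(n_genes) or n_genes == "" else int(n_genes)
        label = getattr(r, "cytoband", None)
        label = None if pd.isna(label) or label == "" else str(label)
        regions.append(
            RecurrentRegion(
                chrom=normalize_chrom(r.chrom), start=int(r.start),
                stop=int(r.stop), direction=str(r.direction),
                n_cases=int(r.n_cases), denominator=int(r.denominator),
                frequency=int(r.n_cases) / int(r.denominator),
                label=label, n_genes=n_genes,
            )
        )
    return regions


# --- BED -------------------------------------------------------------------


def read_bed(path) -> pd.DataFrame:
    """Read a 3+ column BED into a 1-based inclusive interval table.

    BED is 0-based half-open; internal coordinates become (start + 1, stop).
    Negative coordinates and zero-length intervals are parse errors.
    """
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom, start, stop = fields[0], int(fields[1]), int(fields[2])
            if start < 0 or stop < 0:
                raise ParseError(f"{path}: line {lineno}: negative coordinate")
            if stop <= start:
                raise ParseError(f"{path}: line {lineno}: zero-length interval")
            rows.append(
                {"chrom": normalize_chrom(chrom), "start": start + 1,
                 "stop": stop, "name": fields[3] if len(fields) > 3 else ""}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "stop", "name"])


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write a 1-based inclusive interval table back to BED."""
    with open(path, "w") as handle:
        for row in intervals.itertuples(index=False):
            name = getattr(row, "name", "")
            fields = [row.chrom, str(int(row.start) - 1), str(int(row.stop))]
            if name:
                fields.append(str(name))
            handle.write("\t".join(fields) + "\n")


# --- GMT -------------------------------------------------------------------


def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT needs name, description, genes"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path) -> None:
    with open(path, "w") as handle:
        for name, genes in sets.items():
            handle.write("\t".join([name, name, *sorted(genes)]) + "\n")


# --- target predictions ----------------------------------------------------


def read_target_predictions(path, database: str | None = None) -> TargetPredictionSet:
    """Read a per-database miRNA->gene TSV (columns: mirna, gene[, score])."""
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, ["mirna", "gene"], path)
    name = database or Path(path).stem
    return TargetPredictionSet.from_pairs(
        name, zip(frame["mirna"].astype(str), frame["gene"].astype(str))
    )


# --- DE table --------------------------------------------------------------


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index=False)


def read_de_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, ["mirna", "log2fc", "p", "q"], path)
    return frame


# --- JSON ------------------------------------------------------------------


def write_json(obj, path) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=1, default=str)


def read_json(path):
    with open(path) as handle:
        return json.load(handle)
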