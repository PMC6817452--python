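"""Copy-number segment calling and recurrent-region analysis.

Per-sample aCGH probe log2 ratios (test vs. reference DNA) are reduced to
segment calls by a maximal same-sign run caller with two filters: a minimum
number of probes per aberration and a minimum absolute mean log2 ratio.
Cross-case recurrence is then computed on atomic intervals (between the union
of all segment breakpoints) so that region penetrance is exact at every base.

Coordinates are 1-based inclusive throughout; gains and losses are aggregated
separately, so a base may belong to one gain region and one loss region
across different cases.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SegmentCall",
    "CallSummary",
    "RecurrentRegion",
    "call_segments",
    "summarize_calls",
    "recurrent_regions",
    "genes_in_regions",
    "region_report",
]

#: default aberration filters: minimum probes per call and |mean log2 ratio|
DEFAULT_MIN_PROBES = 3
DEFAULT_ABS_THRESHOLD = 0.25


@dataclass(frozen=True)
class SegmentCall:
    """One called copy-number aberration in one sample."""

    sample: str
    chrom: str
    start: int  # 1-based inclusive
    stop: int  # 1-based inclusive
    direction: str  # "gain" | "loss"
    mean_log2: float
    n_probes: int

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValueError(
                f"segment start {self.start} > stop {self.stop} "
                f"({self.sample} {self.chrom})"
            )
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be gain|loss, got {self.direction!r}")


@dataclass(frozen=True)
class RecurrentRegion:
    """A genomic interval recurrently altered in the same direction.

    ``frequency`` (penetrance) is ``n_cases / denominator`` where the
    denominator is the number of cases with at least one significant segment,
    the convention under which printed percentages such as 7/16 = 43.75%
    reconcile.
    """

    chrom: str
    start: int
    stop: int
    direction: str
    n_cases: int
    denominator: int
    frequency: float
    label: str | None = None
    n_genes: int | None = None

    def overlaps(self, chrom: str, start: int, stop: int) -> bool:
        return self.chrom == chrom and start <= self.stop and stop >= self.start


@dataclass
class CallSummary:
    """Cohort-level call burden: totals and per-group means over flagged cases.

    Means and SDs use the flagged-case denominator (cases with >= 1 call);
    the Welch t-test compares per-case call counts between groups.
    """

    per_sample_counts: pd.Series
    group_totals: dict[str, int]
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_n_flagged: dict[str, int]
    t_statistic: float | None
    p_value: float | None
    groups: tuple[str, str] = field(default=("", ""))


def _probe_signs(values: np.ndarray) -> np.ndarray:
    return np.sign(values).astype(int)


def call_segments(
    probes: pd.DataFrame,
    min_probes: int = DEFAULT_MIN_PROBES,
    abs_threshold: float = DEFAULT_ABS_THRESHOLD,
) -> list[SegmentCall]:
    """Call CNA segments from a probe log2-ratio table.

    Parameters
    ----------
    probes
        Columns ``sample, chrom, position, log2_ratio``; positions strictly
        increasing within each sample x chromosome track.
    min_probes
        Minimum number of probes per emitted run.
    abs_threshold
        Emit a run only if the absolute mean log2 ratio exceeds this value.

    Returns
    -------
    list of :class:`SegmentCall`, one per maximal run of consecutive
    same-sign probes passing both filters. Segment bounds are the first and
    last probe positions of the run; direction is the sign of the run mean.
    """
    if min_probes < 1 or abs_threshold <= 0:
        raise ValueError("min_probes must be >= 1 and abs_threshold > 0")
    required = {"sample", "chrom", "position", "log2_ratio"}
    missing = required - set(probes.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    if probes.empty:
        return []

    calls: list[SegmentCall] = []
    for (sample, chrom), track in probes.groupby(["sample", "chrom"], sort=True):
        pos = track["position"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(
                f"probe positions not strictly increasing for {sample} {chrom}"
            )
        ratios = track["log2_ratio"].to_numpy(dtype=float)
        signs = _probe_signs(ratios)
        idx = 0
        for sign, group in itertools.groupby(signs):
            run_len = len(list(group))
            sl = slice(idx, idx + run_len)
            idx += run_len
            if sign == 0 or run_len < min_probes:
                continue
            mean = float(ratios[sl].mean())
            if abs(mean) <= abs_threshold:
                continue
            calls.append(
                SegmentCall(
                    sample=str(sample),
                    chrom=str(chrom),
                    start=int(pos[sl][0]),
                    stop=int(pos[sl][-1]),
                    direction="gain" if sign > 0 else "loss",
                    mean_log2=mean,
                    n_probes=run_len,
                )
            )
    return calls


def summarize_calls(
    calls: Sequence[SegmentCall],
    group_labels: Mapping[str, str],
) -> CallSummary:
    """Summarize call burden per group and compare the two groups.

    ``group_labels`` maps every sample with calls to one of exactly two group
    names. Group means/SDs are over flagged cases (>= 1 call). The Welch
    t-test is reported as None when a group has fewer than two flagged cases.
    """
    counts: dict[str, int] = defaultdict(int)
    for call in calls:
        if call.sample not in group_labels:
            raise ValueError(f"sample {call.sample!r} has no group label")
        counts[call.sample] += 1
    per_sample = pd.Series(counts, dtype=int).sort_index()
    groups = sorted(set(group_labels.values()))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")

    by_group: dict[str, np.ndarray] = {}
    for g in groups:
        flagged = [s for s in per_sample.index if group_labels[s] == g]
        by_group[g] = per_sample.loc[flagged].to_numpy(dtype=float)

    totals = {g: int(v.sum()) for g, v in by_group.items()}
    means = {g: float(v.mean()) if v.size else float("nan") for g, v in by_group.items()}
    sds = {
        g: float(v.std(ddof=1)) if v.size > 1 else float("nan")
        for g, v in by_group.items()
    }
    n_flagged = {g: int(v.size) for g, v in by_group.items()}

    t_stat: float | None
    p_val: float | None
    a, b = by_group[groups[0]], by_group[groups[1]]
    if a.size >= 2 and b.size >= 2:
        if a.std() == 0 and b.std() == 0:
            # degenerate: identical constant counts -> no evidence of difference
            t_stat, p_val = (0.0, 1.0) if a.mean() == b.mean() else (float("inf"), 0.0)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            t_stat, p_val = float(t), float(p)
    else:
        t_stat, p_val = None, None

    return CallSummary(
        per_sample_counts=per_sample,
        group_totals=totals,
        group_means=means,
        group_sds=sds,
        group_n_flagged=n_flagged,
        t_statistic=t_stat,
        p_value=p_val,
        groups=(groups[0], groups[1]),
    )


def _atoms_for_direction(
    segs: list[SegmentCall],
) -> list[tuple[int, int, frozenset[str]]]:
    """Atomic intervals between the union of breakpoints, with supporting cases."""
    cuts = sorted({s.start for s in segs} | {s.stop + 1 for s in segs})
    atoms = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        start, stop = lo, hi - 1
        support = frozenset(
            s.sample for s in segs if s.start <= start and s.stop >= stop
        )
        if support:
            atoms.append((start, stop, support))
    return atoms


def recurrent_regions(
    calls: Sequence[SegmentCall],
    min_frequency: float = 0.25,
    inclusive_threshold: bool = True,
    denominator: int | None = None,
) -> list[RecurrentRegion]:
    """Find regions altered in the same direction across many cases.

    Per chromosome and direction, atomic intervals are formed from the union
    of all segment breakpoints; each atom's penetrance is the number of
    distinct supporting cases over ``denominator`` (default: number of cases
    with >= 1 call). Atoms meeting the frequency threshold are kept and
    contiguous retained atoms are merged; a merged region's ``n_cases`` is
    the minimum over its atoms, so every base of an emitted region is covered
    by at least ``n_cases`` supporting segments.

    ``inclusive_threshold`` keeps atoms at exactly the threshold (the
    convention under which 4/16 = 25.00% regions survive a 25% cut).
    """
    if not calls:
        return []
    if not 0 < min_frequency <= 1:
        raise ValueError("min_frequency must be in (0, 1]")
    denom = denominator if denominator is not None else len({c.sample for c in calls})
    if denom < 1:
        raise ValueError("denominator must be >= 1")

    by_key: dict[tuple[str, str], list[SegmentCall]] = defaultdict(list)
    for c in calls:
        by_key[(c.chrom, c.direction)].append(c)

    regions: list[RecurrentRegion] = []
    for (chrom, direction), segs in sorted(by_key.items()):
        atoms = _atoms_for_direction(segs)
        retained = []
        for start, stop, support in atoms:
            freq = len(support) / denom
            keep = freq >= min_frequency if inclusive_threshold else freq > min_frequency
            if keep:
                retained.append((start, stop, len(support)))
        # merge contiguous retained atoms
        merged: list[list[int]] = []
        for start, stop, n in retained:
            if merged and merged[-1][1] + 1 == start:
                merged[-1][1] = stop
                merged[-1][2] = min(merged[-1][2], n)
            else:
                merged.append([start, stop, n])
        for start, stop, n in merged:
            regions.append(
                RecurrentRegion(
                    chrom=chrom,
                    start=start,
                    stop=stop,
                    direction=direction,
                    n_cases=n,
                    denominator=denom,
                    frequency=n / denom,
                )
            )
    regions.sort(key=lambda r: (_chrom_sort_key(r.chrom), r.start, r.direction))
    return regions


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    name = chrom.removeprefix("chr")
    if name.isdigit():
        return (int(name), "")
    return (100, name)


def genes_in_regions(
    regions: Sequence[RecurrentRegion],
    annotations: pd.DataFrame,
) -> list[list[str]]:
    """Assign annotated genes to regions by any-overlap (>= 1 base).

    ``annotations`` has columns ``symbol, chrom, start, stop`` on the same
    1-based inclusive convention. A gene abutting a region end (gene start ==
    region stop) counts as a 1-bp overlap. Returns per-region gene symbol
    lists aligned with ``regions``.
    """
    if annotations.empty:
        return [[] for _ in regions]
    required = {"symbol", "chrom", "start", "stop"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    out: list[list[str]] = []
    for region in regions:
        mask = (
            (annotations["chrom"] == region.chrom)
            & (annotations["start"] <= region.stop)
            & (annotations["stop"] >= region.start)
        )
        out.append(annotations.loc[mask, "symbol"].tolist())
    return out


def region_report(
    regions: Sequence[RecurrentRegion],
    gene_counts: Sequence[int] | None = None,
) -> dict:
    """Gain/loss composition and gene-count totals for a region set.

    ``gene_counts`` defaults to each region's ``n_genes`` attribute when set.
    Returns a dict with the fraction of regions by direction (percent), a
    per-region frequency table, and total/min/max gene counts when available.
    """
    if not regions:
        raise ValueError("region_report requires a non-empty region list")
    n = len(regions)
    n_gain = sum(1 for r in regions if r.direction == "gain")
    if gene_counts is None:
        counts = [r.n_genes for r in regions]
        gene_counts = None if any(c is None for c in counts) else counts  # type: ignore[assignment]
    table = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "label": [r.label for r in regions],
            "start": [r.start for r in regions],
            "stop": [r.stop for r in regions],
            "direction": [r.direction for r in regions],
            "n_cases": [r.n_cases for r in regions],
            "denominator": [r.denominator for r in regions],
            "frequency_pct": [round(100 * r.frequency, 2) for r in regions],
        }
    )
    report = {
        "n_regions": n,
        "pct_gain": round(100 * n_gain / n, 1),
        "pct_loss": round(100 * (n - n_gain) / n, 1),
        "frequency_table": table,
    }
    if gene_counts is not None:
        gc = [int(c) for c in gene_counts]
        report.update(
            total_genes=sum(gc), min_genes=min(gc), max_genes=max(gc),
            genes_per_region=gc,
        )
    return report
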