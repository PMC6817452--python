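"""Seeded synthetic cohorts with planted CNAs, dosage-coupled miRNAs and
clinical covariates.

Every downstream stage of the pipeline is exercised against cohorts whose
ground truth is known by construction. Each case carries each configured
CNA region independently with its group's penetrance; probes inside a
carried region shift by +/- 0.58 log2 (a single-copy gain/loss, log2(3/2));
miRNA log2 expression is baseline + subtype effect + dosage coupling for
carried overlapping CNAs + noise, exponentiated and rounded to counts.
Positive controls follow a fixed geometric ladder, negative controls are
low-mean Poisson noise, and a per-sample log2 library shift emulates lane
efficiency (removed again by positive-control normalization). Clinical
covariates are drawn with configurable MCAR missingness.

All distributions are stand-ins for an undeposited cohort and are labeled
as such in the emitted truth record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfigError",
    "RegionSpec",
    "MirnaSpec",
    "CohortConfig",
    "TruthRecord",
    "generate_cohort",
    "default_region_specs",
    "default_mirna_specs",
]

#: single-copy gain/loss mean shift on the log2-ratio scale, log2(3/2)
SINGLE_COPY_LOG2 = 0.58


class CohortConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


@dataclass(frozen=True)
class RegionSpec:
    """A planted CNA region with per-group penetrance."""

    chrom: str
    start: int
    stop: int
    direction: str  # "gain" | "loss"
    penetrance_a: float
    penetrance_b: float = 0.0


@dataclass(frozen=True)
class MirnaSpec:
    """A planted miRNA: locus, baseline abundance and effects."""

    name: str
    chrom: str
    start: int
    stop: int
    baseline_log2: float
    subtype_log2fc: float
    dosage_coupling: float


def default_region_specs() -> list[RegionSpec]:
    """Planted regions mirroring the reference study's recurrent regions.

    TNBC-group regions get their study penetrance in group A (zero in B);
    non-TNBC regions the reverse.
    """
    from . import datasets

    specs = [
        RegionSpec(r.chrom, r.start, r.stop, r.direction,
                   penetrance_a=r.frequency, penetrance_b=0.0)
        for r in datasets.tnbc_regions()
    ]
    specs += [
        RegionSpec(r.chrom, r.start, r.stop, r.direction,
                   penetrance_a=0.0, penetrance_b=r.frequency)
        for r in datasets.non_tnbc_regions()
    ]
    return specs


def default_mirna_specs(
    baseline_log2: float = 8.0,
    dosage_coupling: float = SINGLE_COPY_LOG2,
) -> list[MirnaSpec]:
    """Planted miRNAs mirroring the 17-miRNA panel (loci and log2FC)."""
    from . import datasets

    loci = datasets.panel_loci()
    table = datasets.panel_table()
    return [
        MirnaSpec(
            name=locus.name,
            chrom=locus.chrom,
            start=int(locus.start),
            stop=int(locus.stop),
            baseline_log2=baseline_log2,
            subtype_log2fc=float(fc),
            dosage_coupling=dosage_coupling,
        )
        for locus, fc in zip(loci.itertuples(index=False), table["log2fc"])
    ]


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the reference study's structure: 25 + 16 cases, the
    published recurrent regions at their published penetrances, the
    17-miRNA panel at its published log2 fold changes, an 800-probe
    endogenous codeset with 6 positive, 6 negative and 5 housekeeping
    controls.
    """

    n_group_a: int = 25
    n_group_b: int = 16
    probe_spacing: int = 1_000_000
    region_specs: list[RegionSpec] = field(default_factory=default_region_specs)
    mirna_specs: list[MirnaSpec] = field(default_factory=default_mirna_specs)
    n_null_mirnas: int = 783
    n_housekeeping: int = 5
    n_positive_controls: int = 6
    n_negative_controls: int = 6
    probe_noise_sd: float = 0.2
    count_noise_sd: float = 0.5
    sample_scale_sd: float = 0.3
    clinical_missing_rate: float = 0.15
    gain_log2: float = SINGLE_COPY_LOG2
    loss_log2: float = -SINGLE_COPY_LOG2
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_group_a", "n_group_b", "n_null_mirnas", "n_housekeeping",
                     "n_positive_controls", "n_negative_controls"):
            if getattr(self, name) < 0:
                raise CohortConfigError(f"{name} must be >= 0")
        if self.probe_spacing < 1:
            raise CohortConfigError("probe_spacing must be >= 1")
        for name in ("probe_noise_sd", "count_noise_sd", "sample_scale_sd"):
            if getattr(self, name) < 0:
                raise CohortConfigError(f"{name} must be >= 0")
        if not 0 <= self.clinical_missing_rate <= 1:
            raise CohortConfigError("clinical_missing_rate must be in [0, 1]")
        for i, spec in enumerate(self.region_specs):
            if spec.start > spec.stop:
                raise CohortConfigError(f"region_specs[{i}] has start > stop")
            if spec.direction not in ("gain", "loss"):
                raise CohortConfigError(f"region_specs[{i}] direction must be gain|loss")
            for pen_name in ("penetrance_a", "penetrance_b"):
                pen = getattr(spec, pen_name)
                if not 0 <= pen <= 1:
                    raise CohortConfigError(
                        f"region_specs[{i}].{pen_name} must be in [0, 1]"
                    )
        for i, spec in enumerate(self.mirna_specs):
            if spec.start > spec.stop:
                raise CohortConfigError(f"mirna_specs[{i}] has start > stop")


@dataclass
class TruthRecord:
    """Ground truth of a generated cohort.

    ``samples``: sample/group table; ``carriers``: one row per (sample,
    region) carriage event; ``mirna_truth``: per-miRNA locus, baseline,
    subtype effect, coupling and null flag. Distributions are synthetic
    stand-ins for the undeposited source cohort.
    """

    samples: pd.DataFrame
    carriers: pd.DataFrame
    mirna_truth: pd.DataFrame
    seed: int
    note: str = (
        "synthetic stand-in cohort; generator distributions are not fit to "
        "any deposited dataset"
    )

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "note": self.note,
            "samples": self.samples.to_dict(orient="records"),
            "carriers": self.carriers.to_dict(orient="records"),
            "mirna_truth": self.mirna_truth.to_dict(orient="records"),
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as handle:
            payload = json.load(handle)
        return cls(
            samples=pd.DataFrame(payload["samples"]),
            carriers=pd.DataFrame(payload["carriers"]),
            mirna_truth=pd.DataFrame(payload["mirna_truth"]),
            seed=payload["seed"],
            note=payload["note"],
        )

    def mirna_loci(self) -> pd.DataFrame:
        t = self.mirna_truth
        return pd.DataFrame(
            {"name": t["name"], "chrom": t["chrom"],
             "start": t["start"], "stop": t["stop"]}
        )


def _clinical_frame(
    samples: list[str], groups: list[str], cfg: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(samples)
    is_a = np.array([g == "TNBC" for g in groups])
    age = rng.normal(56.0, 12.0, size=n)
    while np.any(age < 16):  # truncate at the youngest plausible age
        redo = age < 16
        age[redo] = rng.normal(56.0, 12.0, size=int(redo.sum()))
    size = rng.lognormal(mean=np.log(3.0), sigma=0.45, size=n)
    # group-dependent category probabilities shaped like the study cohort
    p_grade3 = np.where(is_a, 0.48, 0.19)
    p_poor = np.where(is_a, 0.48, 0.15)
    p_node_pos = np.where(is_a, 0.50, 0.88)
    p_ductal = np.full(n, 0.85)
    grade = np.where(rng.random(n) < p_grade3, "III", "I/II")
    stage = np.where(
        rng.random(n) < p_poor, "poorly differentiated",
        "well/moderately differentiated",
    )
    node = np.where(rng.random(n) < p_node_pos, "positive", "negative")
    histology = np.where(rng.random(n) < p_ductal, "ductal", "other")
    frame = pd.DataFrame(
        {
            "sample": samples,
            "group": groups,
            "age": np.round(age, 1),
            "tumor_size": np.round(size, 2),
            "grade": grade,
            "stage": stage,
            "lymph_node": node,
            "histology": histology,
        }
    )
    for col in ("age", "tumor_size", "grade", "stage", "lymph_node", "histology"):
        mask = rng.random(n) < cfg.clinical_missing_rate
        frame.loc[mask, col] = np.nan
    return frame


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate one cohort: probe table, count matrix, clinical table, truth.

    Returns
    -------
    probes
        Long table ``sample, chrom, position, log2_ratio`` covering every
        chromosome named by a region spec, probes every ``probe_spacing``
        bases from 1 to 1.05x the farthest spec coordinate.
    counts
        Probe x sample integer counts with a ``probe_class`` column
        (endogenous | housekeeping | positive | negative).
    clinical
        One row per sample with covariates and MCAR missingness.
    truth
        :class:`TruthRecord` consistent with the emitted matrices.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples = [f"A{i + 1:02d}" for i in range(config.n_group_a)] + [
        f"B{i + 1:02d}" for i in range(config.n_group_b)
    ]
    groups = ["TNBC"] * config.n_group_a + ["non-TNBC"] * config.n_group_b

    # --- carriage draws -----------------------------------------------------
    carrier_rows = []
    carried: dict[str, list[RegionSpec]] = {s: [] for s in samples}
    for region_idx, spec in enumerate(config.region_specs):
        for sample, group in zip(samples, groups):
            pen = spec.penetrance_a if group == "TNBC" else spec.penetrance_b
            if rng.random() < pen:
                carried[sample].append(spec)
                carrier_rows.append(
                    {"sample": sample, "region_index": region_idx,
                     "chrom": spec.chrom, "start": spec.start, "stop": spec.stop,
                     "direction": spec.direction}
                )
    carriers = pd.DataFrame(
        carrier_rows,
        columns=["sample", "region_index", "chrom", "start", "stop", "direction"],
    )

    # --- probe log2 ratios --------------------------------------------------
    chrom_extent: dict[str, int] = {}
    for spec in config.region_specs:
        extent = int(spec.stop * 1.05)
        chrom_extent[spec.chrom] = max(chrom_extent.get(spec.chrom, 0), extent)
    probe_rows = []
    for chrom in sorted(chrom_extent):
        positions = np.arange(1, chrom_extent[chrom] + 1, config.probe_spacing)
        for sample in samples:
            mean = np.zeros(len(positions))
            for spec in carried[sample]:
                if spec.chrom != chrom:
                    continue
                inside = (positions >= spec.start) & (positions <= spec.stop)
                shift = config.gain_log2 if spec.direction == "gain" else config.loss_log2
                mean[inside] += shift
            noise = rng.normal(0.0, config.probe_noise_sd, size=len(positions))
            probe_rows.append(
                pd.DataFrame(
                    {"sample": sample, "chrom": chrom, "position": positions,
                     "log2_ratio": mean + noise}
                )
            )
    probes = (
        pd.concat(probe_rows, ignore_index=True)
        if probe_rows
        else pd.DataFrame(columns=["sample", "chrom", "position", "log2_ratio"])
    )

    # --- miRNA counts -------------------------------------------------------
    shift = rng.normal(0.0, config.sample_scale_sd, size=len(samples))
    mirna_names, mirna_class, rows = [], [], []
    truth_rows = []

    def dosage(sample: str, spec: MirnaSpec) -> float:
        total = 0.0
        for region in carried[sample]:
            if region.chrom == spec.chrom and region.start <= spec.stop and region.stop >= spec.start:
                total += spec.dosage_coupling * (1.0 if region.direction == "gain" else -1.0)
        return total

    for spec in config.mirna_specs:
        log2expr = np.array(
            [
                spec.baseline_log2
                + (spec.subtype_log2fc if group == "TNBC" else 0.0)
                + dosage(sample, spec)
                for sample, group in zip(samples, groups)
            ]
        )
        log2expr = log2expr + shift + rng.normal(0, config.count_noise_sd, len(samples))
        rows.append(np.maximum(np.round(2.0**log2expr), 0.0).astype(int))
        mirna_names.append(spec.name)
        mirna_class.append("endogenous")
        truth_rows.append(
            {"name": spec.name, "chrom": spec.chrom, "start": spec.start,
             "stop": spec.stop, "baseline_log2": spec.baseline_log2,
             "subtype_log2fc": spec.subtype_log2fc,
             "dosage_coupling": spec.dosage_coupling, "is_null": False}
        )

    # null miRNAs live on a quiet contig so they never overlap planted regions
    null_baselines = rng.uniform(4.0, 10.0, size=config.n_null_mirnas)
    for i in range(config.n_null_mirnas):
        name = f"syn-miR-null-{i + 1:03d}"
        start = 1 + i * 10_000
        log2expr = null_baselines[i] + shift + rng.normal(
            0, config.count_noise_sd, len(samples)
        )
        rows.append(np.maximum(np.round(2.0**log2expr), 0.0).astype(int))
        mirna_names.append(name)
        mirna_class.append("endogenous")
        truth_rows.append(
            {"name": name, "chrom": "chrNull", "start": start, "stop": start + 80,
             "baseline_log2": float(null_baselines[i]), "subtype_log2fc": 0.0,
             "dosage_coupling": 0.0, "is_null": True}
        )

    for i in range(config.n_housekeeping):
        log2expr = 10.0 + shift + rng.normal(0, 0.05, len(samples))
        rows.append(np.maximum(np.round(2.0**log2expr), 1.0).astype(int))
        mirna_names.append(f"HK-{i + 1}")
        mirna_class.append("housekeeping")
    ladder = [2.0 ** (13 - 2 * i) for i in range(config.n_positive_controls)]
    for i, base in enumerate(ladder):
        rows.append(np.maximum(np.round(base * 2.0**shift), 1.0).astype(int))
        mirna_names.append(f"POS-{chr(ord('A') + i)}")
        mirna_class.append("positive")
    for i in range(config.n_negative_controls):
        rows.append(rng.poisson(2.0, size=len(samples)))
        mirna_names.append(f"NEG-{chr(ord('A') + i)}")
        mirna_class.append("negative")

    counts = pd.DataFrame(np.vstack(rows), index=mirna_names, columns=samples)
    counts.insert(0, "probe_class", mirna_class)
    counts.index.name = "probe"

    clinical = _clinical_frame(samples, groups, config, rng)
    truth = TruthRecord(
        samples=pd.DataFrame({"sample": samples, "group": groups}),
        carriers=carriers,
        mirna_truth=pd.DataFrame(truth_rows),
        seed=config.seed,
    )
    return probes, counts, clinical, truth
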