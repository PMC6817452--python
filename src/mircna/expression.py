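"""miRNA count normalization, differential expression and clustering.

Normalization follows the three-step nCounter-style scheme: positive-control
scaling (per-sample geometric-mean factor), negative-control background
subtraction (mean + 2 SD, floored at zero), housekeeping content scaling,
then log2(x + 1). Differential expression is a per-miRNA Welch t-test on
log2 values with Benjamini-Hochberg adjustment; hierarchical clustering uses
1 - Pearson correlation distance with average linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NormalizationError",
    "ClusterResult",
    "normalize",
    "differential_expression",
    "bh_adjust",
    "hierarchical_cluster",
]

PROBE_CLASS_COLUMN = "probe_class"
PROBE_CLASSES = ("endogenous", "housekeeping", "positive", "negative")


class NormalizationError(ValueError):
    """Raised when a sample cannot be normalized (e.g. zero controls)."""


def _geomean(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        return 0.0
    return float(np.exp(np.mean(np.log(values))))


def _split_classes(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    if PROBE_CLASS_COLUMN not in raw.columns:
        raise ValueError(f"count matrix needs a {PROBE_CLASS_COLUMN!r} column")
    classes = raw[PROBE_CLASS_COLUMN].astype(str)
    bad = set(classes) - set(PROBE_CLASSES)
    if bad:
        raise ValueError(f"unknown probe classes: {sorted(bad)}")
    counts = raw.drop(columns=[PROBE_CLASS_COLUMN]).astype(float)
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    for cls in ("positive", "negative", "housekeeping"):
        if not (classes == cls).any():
            raise ValueError(f"normalization requires >= 1 {cls} probe")
    return counts, classes


def _scale_factors(counts: pd.DataFrame, step: str) -> pd.Series:
    """Per-sample factor = cohort geometric mean / sample geometric mean."""
    gms = counts.apply(lambda col: _geomean(col.to_numpy()), axis=0)
    for sample, gm in gms.items():
        if gm <= 0:
            raise NormalizationError(
                f"sample {sample!r} has zero {step} geometric mean"
            )
    reference = float(np.exp(np.mean(np.log(gms.to_numpy()))))
    return reference / gms


def normalize(raw: pd.DataFrame) -> pd.DataFrame:
    """Normalize a raw count matrix; returns log2 endogenous values.

    Parameters
    ----------
    raw
        Rows are probes (index = probe names) with a ``probe_class`` column
        in {endogenous, housekeeping, positive, negative}; the remaining
        columns are per-sample non-negative counts.

    Returns
    -------
    DataFrame of endogenous rows x same samples, log2(x + 1) scale.
    """
    counts, classes = _split_classes(raw)

    pos_factor = _scale_factors(counts.loc[classes == "positive"], "positive-control")
    scaled = counts.mul(pos_factor, axis=1)

    neg = scaled.loc[classes == "negative"]
    background = neg.mean(axis=0) + 2 * neg.std(axis=0, ddof=1).fillna(0.0)
    corrected = scaled.sub(background, axis=1).clip(lower=0.0)

    hk_factor = _scale_factors(corrected.loc[classes == "housekeeping"], "housekeeping")
    endo = corrected.loc[classes == "endogenous"].mul(hk_factor, axis=1)
    return np.log2(endo + 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    norm: pd.DataFrame,
    labels: Mapping[str, str],
    group_a: str,
    group_b: str,
    p_max: float = 0.05,
    fdr_max: float = 0.25,
) -> pd.DataFrame:
    """Per-miRNA Welch t-test between two groups on log2 values.

    log2FC is mean(group_a) - mean(group_b), so a positive value means
    up-regulation in ``group_a``. BH adjustment runs across all rows; the
    ``significant`` flag requires both p <= p_max and q <= fdr_max.
    Zero-variance rows with equal group means get p = 1 by convention.
    """
    a_samples = [s for s in norm.columns if labels.get(s) == group_a]
    b_samples = [s for s in norm.columns if labels.get(s) == group_b]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("both groups need >= 2 samples")
    a = norm[a_samples].to_numpy(dtype=float)
    b = norm[b_samples].to_numpy(dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    equal = degenerate & np.isclose(log2fc, 0.0)
    t = np.where(equal, 0.0, t)
    p = np.where(equal, 1.0, p)
    unequal = degenerate & ~np.isclose(log2fc, 0.0)
    t = np.where(unequal, np.where(log2fc > 0, np.inf, -np.inf), t)
    p = np.where(unequal, 0.0, p)

    q = bh_adjust(p)
    result = pd.DataFrame(
        {
            "mirna": norm.index,
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "q": q,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "significant": (p <= p_max) & (q <= fdr_max),
        }
    ).reset_index(drop=True)
    return result


@dataclass
class ClusterResult:
    """Agglomerative clustering output: merge tree and leaf order."""

    linkage_matrix: np.ndarray
    labels: list[str]
    metric: str = "1-pearson"
    method: str = "average"

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage_matrix)]

    def to_newick(self) -> str:
        """Serialize the merge tree to Newick, branch lengths from heights."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def recurse(node, parent_dist: float) -> str:
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = recurse(node.left, node.dist)
            right = recurse(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return recurse(tree, tree.dist) + ";"


def hierarchical_cluster(
    data: pd.DataFrame,
    axis: str = "columns",
) -> ClusterResult:
    """Average-linkage clustering under 1 - Pearson correlation distance.

    ``axis="columns"`` clusters samples over their miRNA profiles,
    ``axis="rows"`` clusters miRNAs over samples. Results are invariant to a
    global affine transform of the profiles (Pearson invariance). A
    zero-variance profile makes the correlation undefined and raises with
    the offending label.
    """
    if axis not in ("columns", "rows"):
        raise ValueError("axis must be 'columns' or 'rows'")
    mat = data.to_numpy(dtype=float).T if axis == "columns" else data.to_numpy(float)
    labels = list(data.columns if axis == "columns" else data.index)
    if mat.shape[0] < 2:
        raise ValueError("need >= 2 profiles to cluster")
    sds = mat.std(axis=1)
    for label, sd in zip(labels, sds):
        if sd == 0:
            raise ValueError(f"profile {label!r} has zero variance")
    dist = 1.0 - np.corrcoef(mat)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return ClusterResult(linkage_matrix=linkage, labels=[str(x) for x in labels])
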