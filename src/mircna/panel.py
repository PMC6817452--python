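"""Discriminatory power of a miRNA panel: ROC/AUC and alteration burden.

The AUC is the Mann-Whitney probability that a positive-class score exceeds
a negative-class score, ties counted one half. Per-miRNA confidence
intervals use the DeLong structural-component variance; the combined panel
score is a standardized logistic combination whose apparent AUC gets a
stratified percentile-bootstrap interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ROCResult",
    "PanelModel",
    "AlterationBurden",
    "auc_mann_whitney",
    "combined_panel_auc",
    "alteration_burden",
    "per_mirna_auc",
]


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    method: str  # "delong" | "bootstrap"
    oriented: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("CI must contain the AUC point estimate")


def _auc_and_delong_variance(
    pos: np.ndarray, neg: np.ndarray
) -> tuple[float, float]:
    """Tie-aware AUC and DeLong variance from midrank placements."""
    m, n = len(pos), len(neg)
    both = np.concatenate([pos, neg])
    r_all = stats.rankdata(both)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (r_all[:m] - r_pos) / n  # placement of each positive among negatives
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    return float(auc), float(var)


def auc_mann_whitney(
    scores: Sequence[float],
    labels: Sequence[bool],
    orient: bool = True,
) -> ROCResult:
    """AUC with a 95% DeLong confidence interval.

    ``labels`` flags the positive class. With ``orient`` the reported AUC is
    max(auc, 1 - auc) and the ``oriented`` flag records whether the score
    direction was flipped. Degenerate variance (e.g. perfect separation)
    collapses the interval onto the point estimate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    auc, var = _auc_and_delong_variance(pos, neg)
    flipped = False
    if orient and auc < 0.5:
        auc, var = _auc_and_delong_variance(-pos, -neg)
        flipped = True
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return ROCResult(
        auc=auc,
        ci_low=float(np.clip(auc - half, 0.0, 1.0)),
        ci_high=float(np.clip(auc + half, 0.0, 1.0)),
        method="delong",
        oriented=flipped,
    )


def per_mirna_auc(
    norm: pd.DataFrame,
    labels: Mapping[str, str],
    positive_group: str,
    orient: bool = True,
) -> pd.DataFrame:
    """Oriented AUC with DeLong CI for every miRNA row of ``norm``."""
    y = np.array([labels[s] == positive_group for s in norm.columns])
    rows = []
    for mirna, values in norm.iterrows():
        res = auc_mann_whitney(values.to_numpy(float), y, orient=orient)
        rows.append(
            {
                "mirna": mirna,
                "auc": res.auc,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "oriented": res.oriented,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PanelModel:
    """Standardized logistic combination of panel miRNAs."""

    mirnas: list[str]
    weights: np.ndarray
    intercept: float
    means: np.ndarray
    sds: np.ndarray
    ridge_fallback: bool = False

    def score(self, norm: pd.DataFrame) -> pd.Series:
        """Linear predictor for each sample column of ``norm``."""
        x = norm.loc[self.mirnas].to_numpy(float).T
        z = (x - self.means) / self.sds
        return pd.Series(self.intercept + z @ self.weights, index=norm.columns)


def _fit_logistic(z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Unpenalized logistic MLE; ridge-stabilized fallback on separation."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y.astype(float), sm.add_constant(z, has_constant="add")).fit(
                disp=0, maxiter=200
            )
        params = np.asarray(res.params, dtype=float)
        converged = bool(res.mle_retvals.get("converged", True))
        if converged and np.all(np.abs(params) < 50) and np.all(np.isfinite(params)):
            return params[1:], float(params[0]), False
    except Exception:
        pass
    clf = LogisticRegression(C=10.0, solver="lbfgs", max_iter=1000)
    clf.fit(z, y.astype(int))
    return clf.coef_[0].astype(float), float(clf.intercept_[0]), True


def combined_panel_auc(
    norm_panel: pd.DataFrame,
    labels: Mapping[str, str],
    positive_group: str,
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[PanelModel, ROCResult]:
    """Fit the combined panel score and report its apparent AUC.

    Each miRNA is standardized (mean 0, SD 1) before an unpenalized logistic
    fit; under perfect separation a ridge-stabilized fit (small fixed
    penalty) substitutes and is flagged on the model. The 95% interval is a
    stratified percentile bootstrap over samples (class counts preserved),
    refitting the combination on every replicate.
    """
    y = np.array([labels[s] == positive_group for s in norm_panel.columns])
    if y.sum() < 3 or (~y).sum() < 3:
        raise ValueError("both classes need >= 3 samples")
    x = norm_panel.to_numpy(float).T
    means, sds = x.mean(axis=0), x.std(axis=0, ddof=0)
    if np.any(sds == 0):
        flat = [m for m, sd in zip(norm_panel.index, sds) if sd == 0]
        raise ValueError(f"panel miRNAs with zero variance: {flat}")
    z = (x - means) / sds

    weights, intercept, ridge = _fit_logistic(z, y)
    model = PanelModel(
        mirnas=[str(m) for m in norm_panel.index],
        weights=weights,
        intercept=intercept,
        means=means,
        sds=sds,
        ridge_fallback=ridge,
    )
    scores = z @ weights
    point = auc_mann_whitney(scores, y, orient=False)

    rng = np.random.default_rng(seed)
    pos_idx, neg_idx = np.flatnonzero(y), np.flatnonzero(~y)
    boot_aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [
                rng.choice(pos_idx, size=len(pos_idx), replace=True),
                rng.choice(neg_idx, size=len(neg_idx), replace=True),
            ]
        )
        zb, yb = z[idx], y[idx]
        zb = (zb - zb.mean(axis=0)) / np.where(zb.std(axis=0) == 0, 1, zb.std(axis=0))
        wb, ib, _ = _fit_logistic(zb, yb)
        boot_aucs[b], _ = _auc_and_delong_variance(
            (zb @ wb)[yb], (zb @ wb)[~yb]
        )
    lo, hi = np.percentile(boot_aucs, [2.5, 97.5])
    roc = ROCResult(
        auc=point.auc,
        ci_low=float(min(lo, point.auc)),
        ci_high=float(max(hi, point.auc)),
        method="bootstrap",
    )
    return model, roc


@dataclass
class AlterationBurden:
    """Per-case count of panel miRNAs altered beyond a z threshold."""

    per_case: pd.Series
    group_means: dict[str, float]
    group_ses: dict[str, float]
    p_value: float | None
    z_threshold: float
    skipped_mirnas: list[str] = field(default_factory=list)


def alteration_burden(
    norm: pd.DataFrame,
    panel: pd.DataFrame,
    labels: Mapping[str, str],
    reference_group: str,
    z_threshold: float = 1.96,
) -> AlterationBurden:
    """Count altered panel miRNAs per case, relative to a reference group.

    A panel miRNA is altered in a case when its z-score against the
    reference-group mean/SD exceeds ``z_threshold`` in the direction of that
    miRNA's panel log2FC sign. ``panel`` needs columns ``mirna, log2fc``.
    Zero-SD reference miRNAs are skipped and recorded.
    """
    ref_samples = [s for s in norm.columns if labels.get(s) == reference_group]
    if len(ref_samples) < 3:
        raise ValueError("reference group needs >= 3 samples")
    burden = pd.Series(0, index=norm.columns, dtype=int)
    skipped: list[str] = []
    for rec in panel.itertuples(index=False):
        if rec.mirna not in norm.index:
            raise KeyError(f"panel miRNA {rec.mirna!r} absent from matrix")
        values = norm.loc[rec.mirna]
        ref = values[ref_samples].to_numpy(float)
        sd = ref.std(ddof=1)
        if sd == 0:
            skipped.append(rec.mirna)
            continue
        zscores = (values - ref.mean()) / sd
        direction = 1.0 if rec.log2fc >= 0 else -1.0
        burden += (direction * zscores > z_threshold).astype(int)

    groups = sorted(set(labels.values()))
    by_group = {
        g: burden[[s for s in burden.index if labels[s] == g]].to_numpy(float)
        for g in groups
    }
    means = {g: float(v.mean()) for g, v in by_group.items() if v.size}
    ses = {
        g: float(v.std(ddof=1) / np.sqrt(v.size))
        for g, v in by_group.items()
        if v.size > 1
    }
    p_value = None
    if len(groups) == 2 and all(v.size >= 2 for v in by_group.values()):
        a, b = by_group[groups[0]], by_group[groups[1]]
        if a.std() == 0 and b.std() == 0:
            p_value = 1.0 if a.mean() == b.mean() else 0.0
        else:
            p_value = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return AlterationBurden(
        per_case=burden,
        group_means=means,
        group_ses=ses,
        p_value=p_value,
        z_threshold=z_threshold,
        skipped_mirnas=skipped,
    )
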