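"""Clinical covariate association with subtype and with miRNA expression.

Group comparisons use a Welch t-test on log-transformed continuous
covariates and a two-sided Fisher exact test on collapsed 2x2 categoricals,
with pairwise deletion of missing values. Per-miRNA covariate-adjusted
linear models are ordinary least squares on log2 expression; missing
covariates are handled either by complete-case analysis or by chained
predictive-mean-matching imputation with Rubin's-rules pooling across
imputed datasets. Tumor grade and stage are never co-adjusted (they overlap
almost completely); the choice is the ``adjust`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .expression import bh_adjust

__all__ = [
    "fisher_exact_2x2",
    "group_compare",
    "encode_covariates",
    "fit_mirna_models",
    "impute_and_pool",
]

#: collapsed category coded 1 for each categorical covariate
CATEGORY_CODING = {
    "grade": "III",
    "stage": "poorly differentiated",
    "lymph_node": "positive",
    "histology": "ductal",
}
CONTINUOUS = ("age", "tumor_size")
CATEGORICAL = ("grade", "stage", "lymph_node", "histology")


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative integers.

    Standard two-sided rule: sum the probabilities of all tables with the
    same margins whose hypergeometric probability does not exceed the
    observed table's. A table with an empty margin carries no information
    and returns p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("cells must be non-negative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def group_compare(records: pd.DataFrame, group_a: str, group_b: str) -> pd.DataFrame:
    """Compare clinical covariates between two groups, variable by variable.

    ``records`` has a ``group`` column plus the covariates in
    :data:`CONTINUOUS` (Welch t on log-transformed values) and
    :data:`CATEGORICAL` (two-sided Fisher exact on the collapsed 2x2).
    Missing values are dropped per variable, so each row reports its own n.
    """
    in_a = records["group"] == group_a
    in_b = records["group"] == group_b
    if not in_a.any() or not in_b.any():
        raise ValueError("both groups must be non-empty")
    rows = []
    for var in CONTINUOUS:
        if var not in records.columns:
            continue
        a = records.loc[in_a, var].dropna().astype(float)
        b = records.loc[in_b, var].dropna().astype(float)
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError(f"{var} must be positive for the log transform")
        if len(a) >= 2 and len(b) >= 2:
            t, p = stats.ttest_ind(np.log(a), np.log(b), equal_var=False)
            stat, pval = float(t), float(p)
        else:
            stat, pval = np.nan, np.nan
        rows.append(
            {"variable": var, "test": "welch_t_log", "n_a": len(a), "n_b": len(b),
             "statistic": stat, "p": pval, "note": ""}
        )
    for var in CATEGORICAL:
        if var not in records.columns:
            continue
        level = CATEGORY_CODING[var]
        a = records.loc[in_a, var].dropna()
        b = records.loc[in_b, var].dropna()
        table = np.array(
            [
                [int((a == level).sum()), int((a != level).sum())],
                [int((b == level).sum()), int((b != level).sum())],
            ]
        )
        empty_margin = bool(
            np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0)
        )
        rows.append(
            {"variable": var, "test": "fisher_exact", "n_a": len(a), "n_b": len(b),
             "statistic": np.nan, "p": fisher_exact_2x2(table),
             "note": "empty margin" if empty_margin else ""}
        )
    return pd.DataFrame(rows)


def encode_covariates(records: pd.DataFrame, adjust: str = "grade") -> pd.DataFrame:
    """Numeric design frame: subtype indicator plus adjustment covariates.

    Binary categoricals are coded 1 for the :data:`CATEGORY_CODING` level.
    ``adjust`` picks grade or stage; the other is dropped. Missing entries
    stay NaN for downstream complete-case or imputation handling.
    """
    if adjust not in ("grade", "stage"):
        raise ValueError("adjust must be 'grade' or 'stage'")
    groups = sorted(records["group"].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"expected two groups, got {groups}")
    # the lexicographically smaller group name is coded 1 (TNBC before non-TNBC)
    positive = groups[0]
    out = pd.DataFrame(index=records.index)
    out["subtype"] = (records["group"] == positive).astype(float)
    for var in CONTINUOUS:
        if var in records.columns:
            out[var] = records[var].astype(float)
    for var in ("lymph_node", "histology", adjust):
        if var in records.columns:
            level = CATEGORY_CODING[var]
            coded = records[var].map(lambda v: np.nan if pd.isna(v) else float(v == level))
            out[var] = coded
    return out


def _check_design(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        aliased = []
        kept: list[int] = []
        for j in range(x.shape[1]):
            if np.linalg.matrix_rank(x[:, kept + [j]]) == len(kept):
                aliased.append(names[j])
            else:
                kept.append(j)
        raise ValueError(f"rank-deficient design; aliased covariates: {aliased}")


def _ols_subtype(
    y: np.ndarray, design: pd.DataFrame
) -> tuple[float, float, float, int]:
    """OLS of y on the design; returns subtype coef, SE, p and residual df."""
    x = sm.add_constant(design.to_numpy(float), has_constant="add")
    _check_design(x, ["const", *design.columns])
    fit = sm.OLS(y, x).fit()
    j = 1 + list(design.columns).index("subtype")
    return float(fit.params[j]), float(fit.bse[j]), float(fit.pvalues[j]), int(fit.df_resid)


def fit_mirna_models(
    norm: pd.DataFrame,
    records: pd.DataFrame,
    adjust: str = "grade",
) -> pd.DataFrame:
    """Complete-case covariate-adjusted OLS per miRNA.

    Outcome: log2 expression of each ``norm`` row; covariates: subtype,
    age, tumor size, lymph node, histology, and grade or stage. Reports the
    subtype coefficient with SE, p and a BH q across the panel, on the cases
    complete for all covariates.
    """
    design_all = encode_covariates(records, adjust=adjust)
    design_all.index = records["sample"].astype(str)
    samples = [s for s in norm.columns if s in design_all.index]
    design = design_all.loc[samples]
    complete = design.dropna()
    if len(complete) < design.shape[1] + 3:
        raise ValueError("too few complete cases for the model")
    rows = []
    for mirna, values in norm.iterrows():
        y = values[complete.index].to_numpy(float)
        coef, se, p, df = _ols_subtype(y, complete)
        rows.append({"mirna": mirna, "coef": coef, "se": se, "p": p,
                     "df": df, "n": len(complete)})
    result = pd.DataFrame(rows)
    result["q"] = bh_adjust(result["p"].to_numpy())
    return result


# ---------------------------------------------------------------------------
# chained-equations imputation with predictive mean matching


def _pmm_impute(
    data: pd.DataFrame,
    rng: np.random.Generator,
    n_iter: int = 10,
    k_donors: int = 5,
) -> pd.DataFrame:
    """One imputed copy of ``data`` via chained PMM.

    Each incomplete column is regressed on the others (posterior-draw
    coefficients, type-1 matching); every missing entry receives the
    observed value of one of the ``k_donors`` nearest predicted neighbours.
    Because donors are observed values, binary 0/1 columns stay binary.
    """
    filled = data.copy()
    miss = {c: data[c].isna().to_numpy() for c in data.columns}
    incomplete = [c for c in data.columns if miss[c].any()]
    for c in incomplete:
        if miss[c].all():
            raise ValueError(f"covariate {c!r} is missing in every record")
        obs_vals = data.loc[~miss[c], c].to_numpy(float)
        filled.loc[miss[c], c] = rng.choice(obs_vals, size=int(miss[c].sum()))
    for _ in range(n_iter):
        for c in incomplete:
            m = miss[c]
            others = [col for col in data.columns if col != c]
            x = np.column_stack(
                [np.ones(len(filled)), filled[others].to_numpy(float)]
            )
            y = filled[c].to_numpy(float)
            xo, yo = x[~m], y[~m]
            xtx = xo.T @ xo
            xtx_inv = np.linalg.pinv(xtx)
            beta_hat = xtx_inv @ xo.T @ yo
            resid = yo - xo @ beta_hat
            df_res = max(len(yo) - x.shape[1], 1)
            sigma2 = float(resid @ resid) / df_res
            sigma2_draw = sigma2 * df_res / max(rng.chisquare(df_res), 1e-12)
            cov = sigma2_draw * xtx_inv
            try:
                chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
                beta_draw = beta_hat + chol @ rng.standard_normal(len(beta_hat))
            except np.linalg.LinAlgError:
                beta_draw = beta_hat
            pred_obs = xo @ beta_hat
            pred_mis = x[m] @ beta_draw
            donors = np.empty(int(m.sum()))
            for i, pm in enumerate(pred_mis):
                nearest = np.argsort(np.abs(pred_obs - pm), kind="stable")[:k_donors]
                donors[i] = yo[rng.choice(nearest)]
            vals = filled[c].to_numpy(float)
            vals[m] = donors
            filled[c] = vals
    return filled


@dataclass(frozen=True)
class PooledRegressionResult:
    mirna: str
    coef: float
    se: float
    p: float
    q: float
    n_imputations: int
    adjust: str


def impute_and_pool(
    norm: pd.DataFrame,
    records: pd.DataFrame,
    n_imputations: int = 10,
    seed: int | None = None,
    adjust: str = "grade",
    n_iter: int = 10,
    k_donors: int = 5,
) -> pd.DataFrame:
    """Multiply-impute missing covariates and pool per-miRNA OLS by Rubin.

    ``n_imputations`` independent chained-PMM imputations of the covariate
    frame are drawn (miRNA outcomes must be complete); the subtype
    coefficient is pooled with total variance W + (1 + 1/m) B. With zero
    missingness every imputed dataset equals the complete data, B = 0, and
    the pooled results coincide exactly with the complete-case fit.
    """
    design_all = encode_covariates(records, adjust=adjust)
    design_all.index = records["sample"].astype(str)
    samples = [s for s in norm.columns if s in design_all.index]
    design = design_all.loc[samples]
    if norm[samples].isna().any().any():
        raise ValueError("miRNA outcome values must be complete")

    rng = np.random.default_rng(seed)
    imputed = [
        _pmm_impute(design, rng, n_iter=n_iter, k_donors=k_donors)
        for _ in range(n_imputations)
    ]

    rows = []
    for mirna, values in norm.iterrows():
        y = values[samples].to_numpy(float)
        coefs = np.empty(n_imputations)
        variances = np.empty(n_imputations)
        df_complete = None
        for i, dset in enumerate(imputed):
            coef, se, _, df = _ols_subtype(y, dset)
            coefs[i], variances[i] = coef, se**2
            df_complete = df
        qbar = coefs.mean()
        w = variances.mean()
        b = coefs.var(ddof=1) if n_imputations > 1 else 0.0
        total = w + (1 + 1 / n_imputations) * b
        se_pooled = float(np.sqrt(total))
        if b == 0.0:
            # no between-imputation variance: identical to the complete fit
            df_use = float(df_complete)
        else:
            df_use = (n_imputations - 1) * (1 + w / ((1 + 1 / n_imputations) * b)) ** 2
        tval = qbar / se_pooled if se_pooled > 0 else np.inf
        p = float(2 * stats.t.sf(abs(tval), df_use))
        rows.append(
            {"mirna": mirna, "coef": float(qbar), "se": se_pooled, "p": p,
             "n_imputations": n_imputations, "adjust": adjust}
        )
    result = pd.DataFrame(rows)
    result["q"] = bh_adjust(result["p"].to_numpy())
    return result
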