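"""Associate panel expression with subtype, adjusted for clinical covariates.

Group comparisons (Welch t on log values, Fisher exact on collapsed 2x2s)
are followed by per-miRNA OLS models; missing covariates are multiply
imputed (chained PMM, 10 datasets) and pooled by Rubin's rules with BH FDR
on the subtype coefficient.
"""

from mircna import clinical, expression, simulate

config = simulate.CohortConfig(
    n_group_a=19, n_group_b=24, clinical_missing_rate=0.15, seed=3
)
_, counts, records, truth = simulate.generate_cohort(config)
norm = expression.normalize(counts)

comparison = clinical.group_compare(records, "TNBC", "non-TNBC")
print("covariate comparisons (pairwise deletion):")
print(comparison[["variable", "test", "n_a", "n_b", "p"]].round(4)
      .to_string(index=False))

planted = truth.mirna_truth.loc[~truth.mirna_truth["is_null"], "name"]
pooled = clinical.impute_and_pool(
    norm.loc[planted], records, n_imputations=10, seed=1, adjust="grade"
)
n_sig = int((pooled["q"] <= 0.05).sum())
print(f"\npooled models (adjust = grade): {n_sig}/{len(pooled)} miRNAs "
      "associated with subtype at FDR 0.05")
print(pooled.nsmallest(5, "q")[["mirna", "coef", "se", "p", "q"]].round(4)
      .to_string(index=False))
# Subtype coefficients approximate the planted log2 fold changes; most
# planted miRNAs stay significant after covariate adjustment.
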