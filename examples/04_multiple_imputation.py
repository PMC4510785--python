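"""Multivariate-normal multiple imputation with Rubin's rules.

Masks 15% of the risk-factor measurements completely at random, imputes
m=5 completed cohorts by multivariate-normal data augmentation, and pools
the intensive-arm mean HbA1c across imputations with Rubin's rules,
comparing against the withheld truth.
"""

import diabcea as d
from diabcea.imputation import ImputationConfig

cfg = d.default_config(seed=41)
cohort = d.generate_cohort(cfg)
masked, truth = d.inject_missingness(cohort, missing_rate=0.15, seed=42)

n_missing = masked["hba1c_y0"].isna().sum()
print(f"masked cells in baseline HbA1c: {n_missing} of {len(masked)}")

sets = d.impute(masked, ImputationConfig(m=5, burn_in=200, thin=100, seed=43))

sel = lambda df: df.loc[df["arm"] == "intensive", "hba1c_y0"]
ests = [sel(s).mean() for s in sets]
variances = [sel(s).var(ddof=1) / len(sel(s)) for s in sets]
pooled = d.rubins_pool(ests, variances)

print(f"per-imputation means : {[round(e, 3) for e in ests]}")
print(
    f"pooled mean {pooled.estimate:.3f}  (95% CI {pooled.ci_low:.3f}-{pooled.ci_high:.3f}, "
    f"between-imputation var {pooled.between_variance:.2e})"
)
print(f"withheld truth       : {sel(truth).mean():.3f}")
print(
    "\nThe pooled CI should cover the truth; the between-imputation variance\n"
    "term widens it to reflect the uncertainty added by the missing cells."
)
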