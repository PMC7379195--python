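"""Recompute the published informed-prior Bayes factors.

Each row takes a published effect estimate (mean difference and 95% CI,
n = 26), recovers the standard error from the CI, models the likelihood
as a t distribution (df = 25) and integrates it against the published
uniform prior. BF01 > 1 favors the null hypothesis of no condition
difference; the preregistered corrected-MMN analysis gives BF01 ~ 6.25
(moderate evidence that cascade and no-repetition controls yield the
same corrected MMN), while the N1 analyses are inconclusive to
moderately null depending on the prior.
"""

from mmnlab import run_reproduction

table, ok = run_reproduction()
print(table[["analysis", "mean_uv", "prior", "bf01", "reported_bf01",
             "label"]].to_string(index=False,
                                 float_format=lambda v: f"{v:.3f}"))
print(f"\nall recomputed BF01 within 5% of published values: {ok}")
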