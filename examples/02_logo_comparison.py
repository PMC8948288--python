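"""Compare seed sequence logos between two groups with the multinomial
mixed-effects model.

Simulates 100 seeds per group where the second group's odds of A vs G are
2.5x the first group's, fits the mixed model with a per-seed random
intercept, and reports group odds ratios and the group-by-position
interaction test.
"""

import numpy as np

import seedtox as st
from seedtox.logo import GLMMSpec, test_effect

gen = st.LogoGenerator(
    group_logor={"mouse": (np.log(2.5), 0.0, 0.0)},  # planted OR_A = 2.5
    n_seeds_per_group=100,
    sigma_true=0.25,
    rng_seed=7,
)
data = st.gen_logo_data(gen)

fit = st.fit_multinomial_glmm(data, GLMMSpec(covariance="diagonal"))
print(f"fit converged={fit.converged}, log-likelihood {fit.loglik:.1f}, "
      f"{fit.n_clusters} seeds x 6 positions")

ors = st.group_odds_ratios(fit, "mouse", "human")
print("\nodds of each nucleotide vs G, mouse relative to human:")
print(ors.round(3).to_string())
print("-> OR_A should be near the planted 2.5; C and U near 1.")

reduced = st.fit_multinomial_glmm(
    data, GLMMSpec(covariance="diagonal", include_interaction=False)
)
lr, df, p = test_effect(fit, reduced)
print(f"\ngroup x position interaction: LR = {lr:.2f}, df = {df}, p = {p:.3f}")
print("-> no interaction was planted, so p should usually be non-significant.")
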