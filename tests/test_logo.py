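"""Multinomial mixed model: pooled limits, invariants and LR tests.

Heavier parameter-recovery simulations live in the acceptance suite; these
tests exercise the model mechanics at small n.
"""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

import statsmodels.api as sm

from seedtox.logo import (
    ConvergenceError,
    GLMMSpec,
    SeparationWarning,
    _LogoGLMM,
    fit_multinomial_glmm,
    group_odds_ratios,
    loglik_at,
    long_table_from_seeds,
    validate_logo_table,
)
from seedtox.logo import test_effect as effect_lr_test
from seedtox.simulate import LogoGenerator, gen_logo_data


@pytest.fixture(scope="module")
def small_two_group():
    gen = LogoGenerator(
        n_seeds_per_group=60,
        sigma_true=0.2,
        group_logor={"mouse": (np.log(2.0), 0.3, 0.0)},
        rng_seed=21,
    )
    return gen_logo_data(gen)


@pytest.fixture(scope="module")
def pooled_data():
    gen = LogoGenerator(n_seeds_per_group=80, sigma_true=0.0, rng_seed=22)
    return gen_logo_data(gen)


class TestTableHandling:
    def test_long_table_from_seeds_shape(self):
        df = long_table_from_seeds({"h": ["GGGGGC"], "m": ["AAAAAA", "ACGUAC"]})
        assert len(df) == 18
        assert set(df["group"]) == {"h", "m"}
        assert df.groupby("seed_id").size().eq(6).all()

    def test_incomplete_seed_rejected(self):
        df = long_table_from_seeds({"h": ["GGGGGC"]}).iloc[:-1]
        with pytest.raises(ValueError, match="6 position"):
            validate_logo_table(df)

    def test_invalid_nucleotide_rejected(self):
        df = long_table_from_seeds({"h": ["GGGGGC"]})
        df.loc[0, "nucleotide"] = "X"
        with pytest.raises(ValueError, match="invalid"):
            validate_logo_table(df)


class TestPooledLimit:
    def test_matches_independent_multinomial_logit(self, pooled_data):
        """With no random effect the fit is the pooled multinomial MLE."""
        spec = GLMMSpec(covariance="none")
        fit = fit_multinomial_glmm(pooled_data, spec)
        model = _LogoGLMM(pooled_data, spec)
        R = model.X.reshape(-1, model.p)
        yflat = model.Y.reshape(-1, model.C)
        ycode = (yflat * np.arange(1, 4)).sum(axis=1).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.MNLogit(ycode, R).fit(disp=0, method="newton", maxiter=200)
        assert np.abs(ref.params.T - fit.beta.values).max() < 1e-6
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_intercept_only_recovers_category_proportions(self, pooled_data):
        spec = GLMMSpec(
            covariance="none",
            include_group=False,
            include_position=False,
            include_interaction=False,
        )
        fit = fit_multinomial_glmm(pooled_data, spec)
        eta = np.concatenate([[0.0], fit.beta["intercept"].to_numpy()])
        probs = np.exp(eta) / np.exp(eta).sum()  # G, A, C, U
        obs = pooled_data["nucleotide"].value_counts(normalize=True)
        for base, p in zip("GACU", probs):
            assert p == pytest.approx(obs[base], abs=1e-6)

    def test_reference_relabeling_equivariance(self, pooled_data):
        """OR_{A vs G} = OR_{A vs C} * OR_{C vs G} for the group contrast."""
        fit_g = fit_multinomial_glmm(pooled_data, GLMMSpec(covariance="none"))
        fit_c = fit_multinomial_glmm(
            pooled_data, GLMMSpec(covariance="none", reference_nucleotide="C")
        )
        or_g = group_odds_ratios(fit_g, "mouse", "human")
        or_c = group_odds_ratios(fit_c, "mouse", "human")
        assert or_g.loc["A", "OR"] == pytest.approx(
            or_c.loc["A", "OR"] * or_g.loc["C", "OR"], rel=1e-6
        )


class TestMixedFit:
    def test_loglik_above_null_parameters(self, small_two_group):
        spec = GLMMSpec(covariance="diagonal")
        fit = fit_multinomial_glmm(small_two_group, spec)
        assert fit.converged
        null = loglik_at(
            small_two_group,
            spec,
            np.zeros_like(fit.beta.values),
            np.full(3, np.log(1e-3)),
        )
        assert fit.loglik >= null

    def test_or_swap_symmetry(self, small_two_group):
        fit = fit_multinomial_glmm(small_two_group, GLMMSpec(covariance="diagonal"))
        ab = group_odds_ratios(fit, "mouse", "human")
        ba = group_odds_ratios(fit, "human", "mouse")
        assert np.allclose(ab["OR"].to_numpy(), 1.0 / ba["OR"].to_numpy())
        assert np.allclose(ab["ci_low"].to_numpy(), 1.0 / ba["ci_high"].to_numpy())

    def test_scalar_agq_close_to_laplace(self, small_two_group):
        lap = fit_multinomial_glmm(
            small_two_group, GLMMSpec(covariance="scalar", method="laplace")
        )
        agq = fit_multinomial_glmm(
            small_two_group, GLMMSpec(covariance="scalar", method="agq", agq_points=11)
        )
        assert abs(lap.loglik - agq.loglik) < 1.0
        assert np.abs(lap.beta.values - agq.beta.values).max() < 0.1

    def test_non_converged_fit_rejected_for_ors(self, small_two_group):
        fit = fit_multinomial_glmm(small_two_group, GLMMSpec(covariance="none"))
        broken = dataclasses.replace(fit, converged=False)
        with pytest.raises(ConvergenceError):
            group_odds_ratios(broken, "mouse", "human")

    def test_separation_warns(self):
        # group "h" never shows U anywhere: a degenerate cell per position
        seeds_h = ["GGGGGC", "GGCAGC", "GGGGGG", "ACGCGC"] * 5
        seeds_m = ["UUUUUU", "ACGUAC", "GGGGGC", "AAGGCC"] * 5
        table = long_table_from_seeds({"h": seeds_h, "m": seeds_m})
        with pytest.warns(SeparationWarning):
            fit_multinomial_glmm(table, GLMMSpec(covariance="none"))


class TestEffectTests:
    def test_identical_fits_give_null_result(self, pooled_data):
        fit = fit_multinomial_glmm(pooled_data, GLMMSpec(covariance="none"))
        lr, df, p = effect_lr_test(fit, fit)
        assert (lr, df, p) == (0.0, 0, 1.0)

    def test_different_data_rejected(self, pooled_data, small_two_group):
        a = fit_multinomial_glmm(pooled_data, GLMMSpec(covariance="none"))
        b = fit_multinomial_glmm(small_two_group, GLMMSpec(covariance="none"))
        with pytest.raises(ValueError, match="same data"):
            effect_lr_test(a, b)

    def test_group_effect_power(self):
        """Strong planted group effect detected in >= 18/20 replicates."""
        rejections = 0
        for rep in range(20):
            data = gen_logo_data(
                LogoGenerator(
                    n_seeds_per_group=200,
                    sigma_true=0.0,
                    group_logor={"mouse": (1.5, 0.0, 0.0)},
                    rng_seed=3000 + rep,
                )
            )
            full = fit_multinomial_glmm(
                data, GLMMSpec(covariance="none", include_interaction=False)
            )
            reduced = fit_multinomial_glmm(
                data,
                GLMMSpec(
                    covariance="none",
                    include_group=False,
                    include_interaction=False,
                ),
            )
            _, df, p = effect_lr_test(full, reduced)
            assert df == 3
            rejections += p < 0.01
        assert rejections >= 18

    def test_interaction_type_i_error_controlled(self):
        """No planted interaction: rejects at alpha=0.05 in <= 3/20 runs."""
        rejections = 0
        for rep in range(20):
            data = gen_logo_data(
                LogoGenerator(
                    n_seeds_per_group=200,
                    sigma_true=0.0,
                    group_logor={"mouse": (0.7, 0.0, 0.0)},
                    rng_seed=4000 + rep,
                )
            )
            full = fit_multinomial_glmm(data, GLMMSpec(covariance="none"))
            reduced = fit_multinomial_glmm(
                data, GLMMSpec(covariance="none", include_interaction=False)
            )
            _, df, p = effect_lr_test(full, reduced)
            assert df == 15
            rejections += p < 0.05
        assert rejections <= 3
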