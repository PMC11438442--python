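"""Mixed models, beta regression, contrasts and adjustments."""

import numpy as np
import pandas as pd
import patsy
import pytest
from scipy import stats as sps

from dazzle.calibration import simulate_behaviour_dataset
from dazzle.stats import (
    BetaMixedRegression,
    adjust_pvalues,
    fit_distance_model,
    fit_motion_model,
    fit_movement_model,
)
from dazzle.stimuli import simulate_motion_observations


@pytest.fixture(scope="module")
def recovery_table():
    return simulate_behaviour_dataset(
        seed=3,
        conditions={("vertical", 0.5): 13.5, ("horizontal", 0.5): 17.7},
        step_sds={("vertical", 0.5): 0.8, ("horizontal", 0.5): 0.8},
        n_fish=6,
        n_rounds=2,
        duration=150.0,
    )


class TestAdjustPvalues:
    def test_tukey_matches_studentized_range(self):
        stats = np.array([2.0, 3.1])
        p = 2 * sps.t.sf(np.abs(stats), 40)
        adj = adjust_pvalues(p, "tukey", stats=stats, k=4, df=40)
        expect = sps.studentized_range.sf(np.sqrt(2) * np.abs(stats), 4, 40)
        assert np.allclose(adj, expect)
        assert np.all(adj >= p)  # adjustment never helps

    def test_two_means_need_no_adjustment(self):
        p = np.array([0.03])
        adj = adjust_pvalues(p, "tukey", stats=np.array([2.3]), k=2, df=50)
        assert np.allclose(adj, p)

    def test_sidak_bounds(self):
        p = np.array([0.01, 0.2])
        adj = adjust_pvalues(p, "sidak", k=5)
        assert np.allclose(adj, 1 - (1 - p) ** 5)


class TestMotionModel:
    def test_constructed_effect_flags_only_the_shifted_bins(self):
        effects = {(90, 0.25, "vertical"): 1.2}
        table = simulate_motion_observations(
            seed=7, n_bins=8, n_fish=4, n_trials=3, effects=effects, noise_sd=0.2
        )
        fit = fit_motion_model(table)
        tab = fit.contrasts.set_index("direction_bin")
        assert tab.loc[90, "p_adj"] < 0.01
        others = tab.drop(index=90)
        assert (others["p_adj"] > 0.01).all()
        # sign: vertical was raised, so horizontal - vertical is negative
        assert tab.loc[90, "estimate"] < 0

    def test_interaction_lrt_detects_direction_specific_effect(self):
        effects = {(0, 0.25, "vertical"): 1.0, (45, 0.25, "vertical"): -1.0}
        table = simulate_motion_observations(seed=8, n_bins=4, n_fish=4, n_trials=3, effects=effects)
        fit = fit_motion_model(table)
        assert fit.lrt["p"] < 0.01

    def test_label_permutation_permutes_but_preserves_pvalues(self):
        table = simulate_motion_observations(seed=9, n_bins=6, n_fish=3, n_trials=2)
        fit = fit_motion_model(table)
        swapped = table.copy()
        swapped["orientation"] = swapped["orientation"].map(
            {"horizontal": "vertical", "vertical": "horizontal"}
        )
        fit2 = fit_motion_model(swapped)
        p1 = np.sort(fit.contrasts["p_adj"].to_numpy())
        p2 = np.sort(fit2.contrasts["p_adj"].to_numpy())
        assert np.allclose(p1, p2, atol=1e-6)
        # estimates flip sign under the label swap
        e1 = fit.contrasts.sort_values("direction_bin")["estimate"].to_numpy()
        e2 = fit2.contrasts.sort_values("direction_bin")["estimate"].to_numpy()
        assert np.allclose(e1, -e2, atol=1e-6)

    def test_negative_strength_rejected(self):
        table = simulate_motion_observations(seed=1, n_bins=2)
        table.loc[0, "strength"] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            fit_motion_model(table)


class TestBetaMixedRegression:
    def test_matches_independent_glmm_oracle(self, recovery_table):
        # Reference values from glmmTMB 1.1.9 (beta family, logit link,
        # (1|fish_id)) fitted to this exact deterministic dataset.
        X = patsy.dmatrix("C(orientation)", recovery_table, return_type="dataframe")
        m = BetaMixedRegression(
            recovery_table["normalised_distance"].to_numpy(),
            X.to_numpy(),
            recovery_table["fish_id"],
        ).fit()
        assert m.loglike == pytest.approx(242.4407, abs=0.01)
        assert m.beta[0] == pytest.approx(-0.028449, abs=1e-3)
        assert m.beta[1] == pytest.approx(-0.492851, abs=1e-3)
        se = np.sqrt(np.diag(m.cov))
        assert se[0] == pytest.approx(0.146102, rel=0.01)
        assert se[1] == pytest.approx(0.046342, rel=0.01)
        assert m.sigma_outer == pytest.approx(0.34899, rel=0.01)
        assert m.phi == pytest.approx(31.889, rel=0.01)

    def test_boundary_responses_rejected(self):
        X = np.ones((4, 1))
        with pytest.raises(ValueError, match="strictly inside"):
            BetaMixedRegression(np.array([0.2, 0.5, 1.0, 0.7]), X, ["a", "a", "b", "b"])

    def test_recovers_simulated_glmm_parameters(self, rng):
        # simulate directly from the model's own generative process
        n_groups, n_per = 12, 40
        beta_true = np.array([-0.4, 0.8])
        sigma_true, phi_true = 0.35, 25.0
        g = np.repeat(np.arange(n_groups), n_per)
        x = rng.random(n_groups * n_per) < 0.5
        X = np.column_stack([np.ones(g.size), x.astype(float)])
        eta = X @ beta_true + rng.normal(0, sigma_true, n_groups)[g]
        mu = 1 / (1 + np.exp(-eta))
        y = rng.beta(mu * phi_true, (1 - mu) * phi_true)
        y = np.clip(y, 1e-4, 1 - 1e-4)
        m = BetaMixedRegression(y, X, g).fit()
        se = np.sqrt(np.diag(m.cov))
        assert m.beta[0] == pytest.approx(beta_true[0], abs=3 * se[0])
        assert m.beta[1] == pytest.approx(beta_true[1], abs=3 * se[1])
        assert m.phi == pytest.approx(phi_true, rel=0.25)
        assert m.sigma_outer == pytest.approx(sigma_true, rel=0.5)


class TestDistanceModel:
    def test_recovers_generating_condition_means(self, recovery_table):
        fit = fit_distance_model(recovery_table)
        mm = fit.marginal_means.set_index("orientation")
        for orientation, truth in (("vertical", 13.5), ("horizontal", 17.7)):
            row = mm.loc[orientation]
            assert row["ci_low_cm"] <= truth <= row["ci_high_cm"]
        ori = fit.contrasts[fit.contrasts["family"] == "orientation_within_size"]
        assert (ori["p_adj"] < 0.05).all()
        assert fit.aic_table.shape[0] == 2
        assert np.isfinite(fit.lrt["p"])

    def test_boundary_responses_rejected(self, recovery_table):
        bad = recovery_table.copy()
        bad.loc[0, "normalised_distance"] = 1.0
        with pytest.raises(ValueError, match="squeeze"):
            fit_distance_model(bad)


class TestMovementModel:
    def test_doubled_step_noise_flagged_with_positive_sign(self):
        table = simulate_behaviour_dataset(
            seed=21,
            conditions={("vertical", 0.5): 15.0, ("horizontal", 0.5): 15.0},
            step_sds={("vertical", 0.5): 1.6, ("horizontal", 0.5): 0.8},
            n_fish=5,
            n_rounds=2,
            duration=120.0,
        )
        fit = fit_movement_model(table)
        ori = fit.contrasts[fit.contrasts["family"] == "orientation_within_size"].iloc[0]
        # horizontal - vertical on the log scale: vertical moved more
        assert ori["estimate"] < 0
        assert ori["p_adj"] < 0.01
        assert 0 <= ori["eta_squared"] <= 1

    def test_zero_movement_bins_handled_by_offset(self, recovery_table):
        table = recovery_table.copy()
        table.loc[:3, "moved_cm"] = 0.0
        fit = fit_movement_model(table)
        assert fit.offset > 0
        assert np.isfinite(fit.result.llf)

    def test_time_candidate_reported_with_aic_and_lrt(self):
        table = simulate_behaviour_dataset(
            seed=21,
            conditions={("vertical", 0.5): 15.0, ("horizontal", 0.5): 15.0},
            step_sds={("vertical", 0.5): 0.8, ("horizontal", 0.5): 0.8},
            n_fish=4,
            n_rounds=2,
            duration=120.0,
        )
        fit = fit_movement_model(table)
        assert fit.aic_table.shape[0] == 2
        assert fit.lrt["comparison"] == "time interaction"
        assert np.isfinite(fit.lrt["p"])


class TestAicParsimony:
    def test_aic_prefers_additive_model_under_null(self):
        # when the direction x orientation interaction is truly absent, AIC
        # should prefer the additive model in the large majority of runs
        wins = 0
        n_sims = 200
        rng = np.random.default_rng(99)
        for _ in range(n_sims):
            table = simulate_motion_observations(
                seed=int(rng.integers(2**31 - 1)), n_bins=8, n_fish=3, n_trials=3
            )
            fit = fit_motion_model(table)
            aic = fit.aic_table["aic"]
            if aic.iloc[-1] <= aic.iloc[0]:  # additive model listed last
                wins += 1
        assert wins / n_sims >= 0.8
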