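"""Posterior-simulation mediation: counterfactual mediator, ACME/ADE
decomposition, and moderated mediation."""

import numpy as np
import pandas as pd
import pytest

from ebep import mediation, ordinal, synthetic
from ebep.mediation import (estimate_mediation_effects, fit_mediator,
                            moderated_mediation_grid,
                            simulate_counterfactual_mediator)
from conftest import make_ordinal_draws


@pytest.fixture(scope="module")
def toy_participants():
    rng = np.random.default_rng(0)
    n = 400
    return pd.DataFrame({
        "participant_id": np.arange(n),
        "treat": rng.integers(0, 2, n).astype(float),
        "binding_z": rng.normal(size=n),
        "individualizing_z": rng.normal(size=n),
    })


class TestCounterfactualMediator:
    def test_zero_noise_zero_coefficients_constant(self, toy_participants):
        df = toy_participants.copy()
        df["pmw_z"] = 1.5  # exact fit: intercept 1.5, all slopes 0
        fit = fit_mediator(df, ("treat", "binding_z"), chains=2, draws=100,
                           seed=1)
        m = simulate_counterfactual_mediator(fit, df, treatment_value=1.0,
                                             seed=2)
        assert np.allclose(m, 1.5)

    def test_treatment_contrast_matches_a_path(self, toy_participants):
        rng = np.random.default_rng(3)
        df = toy_participants.copy()
        df["pmw_z"] = (0.5 * df["treat"] + 0.3 * df["binding_z"]
                       + rng.normal(0, 0.4, len(df)))
        fit = fit_mediator(df, ("treat", "binding_z"), chains=2, draws=400,
                           seed=4)
        eps = np.zeros((fit.stacked("intercept").shape[0], len(df)))
        m1 = simulate_counterfactual_mediator(fit, df, 1.0, noise=eps)
        m0 = simulate_counterfactual_mediator(fit, df, 0.0, noise=eps)
        contrast = (m1 - m0).mean()
        # exactly the posterior mean of the a-path, and near truth within
        # the data realization's sampling error (~0.04)
        assert abs(contrast - fit.stacked("b_treat").mean()) < 1e-10
        assert abs(contrast - 0.5) < 0.12

    def test_moderator_interaction_shifts_contrast(self, toy_participants):
        rng = np.random.default_rng(5)
        df = toy_participants.copy()
        df["pmw_z"] = (0.5 * df["treat"] + 0.3 * df["treat"] * df["binding_z"]
                       + rng.normal(0, 0.4, len(df)))
        fit = fit_mediator(df, ("treat", "binding_z", "treat:binding_z"),
                           chains=2, draws=400, seed=6)
        eps = np.zeros((fit.stacked("intercept").shape[0], len(df)))
        contrasts = {}
        for v in (-1.0, 1.0):
            m1 = simulate_counterfactual_mediator(fit, df, 1.0, "binding_z", v,
                                                  noise=eps)
            m0 = simulate_counterfactual_mediator(fit, df, 0.0, "binding_z", v,
                                                  noise=eps)
            contrasts[v] = (m1 - m0).mean()
        assert abs((contrasts[1.0] - contrasts[-1.0]) - 0.6) < 0.08


class TestMediationEffects:
    def _outcome_draws(self, b_pmw, n_draws=60, **extra):
        betas = {"treat": 0.2, "binding_z": 0.3, "pmw_z": b_pmw}
        betas.update(extra)
        return make_ordinal_draws(
            cutpoints=[-1, 0, 0.7, 1.5, 2.5, 3.5], betas=betas,
            item_effect=[0.3, -0.3, 0.1, -0.1], sd_participant=1.0,
            n_draws=n_draws)

    def _mediator_fit(self, df, terms=("treat", "binding_z"), seed=7,
                      n_draws=60):
        return fit_mediator(df, terms, chains=2, draws=n_draws, seed=seed)

    def test_zero_mediator_path_forces_acme_zero(self, toy_participants):
        rng = np.random.default_rng(8)
        df = toy_participants.copy()
        df["pmw_z"] = 0.5 * df["treat"] + rng.normal(0, 0.5, len(df))
        med = self._mediator_fit(df)
        out = self._outcome_draws(b_pmw=0.0)
        eff = estimate_mediation_effects(med, out, df, threshold=2, n_sims=30,
                                         seed=9)
        assert np.all(eff.draws["acme"] == 0.0)

    def test_linear_toy_matches_product_of_coefficients(self, toy_participants):
        # identity (latent-scale) outcome, no interactions: ACME = a*b,
        # checked against the closed-form product of posterior coefficients
        rng = np.random.default_rng(10)
        df = toy_participants.copy()
        a_true, b_true = 0.6, 0.9
        df["pmw_z"] = a_true * df["treat"] + rng.normal(0, 0.5, len(df))
        med = self._mediator_fit(df, n_draws=400)
        out = self._outcome_draws(b_pmw=b_true, n_draws=400)
        eff = estimate_mediation_effects(med, out, df, threshold=2, n_sims=30,
                                         seed=11, scale="latent")
        a_draws = med.stacked("b_treat")
        closed_form = float((a_draws * b_true).mean())
        assert abs(eff.acme["mean"] - closed_form) < 0.02
        assert abs(eff.acme["mean"] - a_true * b_true) < 0.1

    def test_total_equals_acme_plus_ade_per_draw(self, toy_participants):
        rng = np.random.default_rng(12)
        df = toy_participants.copy()
        df["pmw_z"] = 0.5 * df["treat"] + rng.normal(0, 0.5, len(df))
        med = self._mediator_fit(df)
        out = self._outcome_draws(b_pmw=0.8)
        eff = estimate_mediation_effects(med, out, df, threshold=2, n_sims=20,
                                         seed=13)
        dev = np.abs(eff.draws["total"]
                     - (eff.draws["acme"] + eff.draws["ade"]))
        assert dev.max() < 1e-12

    def test_seed_determinism(self, toy_participants):
        rng = np.random.default_rng(14)
        df = toy_participants.copy()
        df["pmw_z"] = 0.4 * df["treat"] + rng.normal(0, 0.5, len(df))
        med = self._mediator_fit(df)
        out = self._outcome_draws(b_pmw=0.5)
        e1 = estimate_mediation_effects(med, out, df, n_sims=20, seed=15)
        e2 = estimate_mediation_effects(med, out, df, n_sims=20, seed=15)
        assert e1.acme == e2.acme and e1.ade == e2.ade

    def test_mediator_missing_from_outcome_rejected(self, toy_participants):
        df = toy_participants.copy()
        df["pmw_z"] = 0.0
        med = self._mediator_fit(df.assign(pmw_z=np.random.default_rng(1)
                                           .normal(size=len(df))))
        out = make_ordinal_draws(cutpoints=[-1, 0, 1, 2, 3, 4],
                                 betas={"treat": 0.2}, item_effect=[0.0, 0.0])
        with pytest.raises(ValueError, match="mediator"):
            estimate_mediation_effects(med, out, df)

    def test_designed_simulation_acme_excludes_zero_ade_covers(self):
        # a > 0, b > 0, c' = 0: mediated path only
        paths = synthetic.MediationPaths(
            a={"control": 0.0, "violation": 3.4},
            cprime={"control": 0.0, "violation": 0.0}, b=1.2)
        data, _ = synthetic.make_experiment_data(300, design="2-arm",
                                                 paths=paths, seed=16)
        part = data.drop_duplicates("participant_id").reset_index(drop=True)
        med = fit_mediator(part, ("treat", "binding_z", "individualizing_z"),
                           chains=2, draws=250, seed=17)
        spec = ordinal.OrdinalModelSpec(
            fixed_terms=("treat", "binding_z", "individualizing_z", "pmw_z"),
            item_slope_terms=("pmw_z",), chains=2, draws=250, warmup=250,
            seed=18)
        out = ordinal.fit_cumulative_model(data, spec)
        eff = estimate_mediation_effects(med, out, data, threshold=2,
                                         n_sims=50, seed=19)
        assert eff.acme["q2.5"] > 0.0
        assert eff.ade["q2.5"] <= 0.0 <= eff.ade["q97.5"]


class TestModeratedMediation:
    def test_requires_interaction_term(self, toy_participants):
        df = toy_participants.copy()
        rng = np.random.default_rng(20)
        df["pmw_z"] = rng.normal(size=len(df))
        med = fit_mediator(df, ("treat", "binding_z"), chains=2, draws=50,
                           seed=21)
        out = make_ordinal_draws(cutpoints=[-1, 0, 1, 2, 3, 4],
                                 betas={"treat": 0.1, "pmw_z": 0.5},
                                 item_effect=[0.0, 0.0])
        with pytest.raises(ValueError, match="interact"):
            moderated_mediation_grid(med, out, df, moderator="binding_z")

    def test_null_interactions_contrast_covers_zero(self, toy_participants):
        rng = np.random.default_rng(22)
        df = toy_participants.copy()
        df["pmw_z"] = 0.5 * df["treat"] + rng.normal(0, 0.6, len(df))
        med = fit_mediator(df, ("treat", "binding_z", "treat:binding_z"),
                           chains=2, draws=300, seed=23)
        out = make_ordinal_draws(
            cutpoints=[-1, 0, 0.7, 1.5, 2.5, 3.5],
            betas={"treat": 0.2, "binding_z": 0.2, "pmw_z": 0.8,
                   "pmw_z:binding_z": 0.0},
            item_effect=[0.2, -0.2], sd_participant=0.8, n_draws=300,
            jitter=0.01)
        grid = moderated_mediation_grid(med, out, df, moderator="binding_z",
                                        threshold=2, n_sims=30, seed=24)
        assert grid.acme_contrast["q2.5"] <= 0.0 <= grid.acme_contrast["q97.5"]

    def test_positive_interactions_order_acme_levels(self, toy_participants):
        rng = np.random.default_rng(25)
        df = toy_participants.copy()
        df["pmw_z"] = (0.8 * df["treat"] + 0.5 * df["treat"] * df["binding_z"]
                       + rng.normal(0, 0.6, len(df)))
        med = fit_mediator(df, ("treat", "binding_z", "treat:binding_z"),
                           chains=2, draws=200, seed=26)
        out = make_ordinal_draws(
            cutpoints=[-1, 0, 0.7, 1.5, 2.5, 3.5],
            betas={"treat": 0.1, "binding_z": 0.2, "pmw_z": 0.8,
                   "pmw_z:binding_z": 0.4},
            item_effect=[0.2, -0.2], sd_participant=0.8, n_draws=200)
        grid = moderated_mediation_grid(med, out, df, moderator="binding_z",
                                        threshold=2, n_sims=30, seed=27)
        assert grid.high.acme["mean"] > grid.low.acme["mean"]
        assert grid.acme_contrast["q2.5"] > 0.0
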