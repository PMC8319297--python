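"""MrsP small-area estimation: response model, IPF, poststratification,
and gold-standard validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ebep import smallarea, synthetic
from ebep.smallarea import ResponseModelSpec
from conftest import make_smallarea_draws


# ---------------------------------------------------------------------------
# Response model
# ---------------------------------------------------------------------------

class TestResponseModel:
    def test_single_area_degenerate_still_samples(self):
        g = synthetic.make_lattice_geography(1, 1, 1)
        rng = np.random.default_rng(0)
        survey = pd.DataFrame({
            "area_id": "a0_0",
            "gender": rng.choice(["f", "m"], 200),
            "binding_score": rng.normal(3.0, 1.0, 200),
        })
        spec = ResponseModelSpec(demographics=("gender",), chains=2, draws=100,
                                 warmup=100, seed=1)
        fit = smallarea.fit_response_model(survey, g, None, spec)
        assert np.all(np.isfinite(fit.stacked("intercept")))
        assert "rhat" in fit.diagnostics

    def test_demographic_effect_recovery(self, grid_5x5, national_joint):
        pops = {a: 2000 for a in grid_5x5.area_ids}
        cells = synthetic.make_population_cells(grid_5x5, national_joint, 300.0,
                                                pops, seed=2)
        latent, _ = synthetic.draw_latent_surface(grid_5x5, 0.5, 0.2, 0.8, seed=3)
        effects = {
            "gender": {"female": -0.15, "male": 0.15},
            "age": {"18-34": -0.2, "35-54": 0.0, "55+": 0.2},
            "ethnicity": {"white": 0.1, "black": -0.2, "hispanic": 0.0,
                          "other": -0.1},
            "education": {"hs_or_less": -0.3, "some_college": 0.0, "college": 0.3},
            "attendance": {"never": -0.25, "sometimes": 0.0, "weekly": 0.35},
            "ideology": {"liberal": -0.6, "moderate": 0.0, "conservative": 0.6},
        }
        survey, _ = synthetic.sample_biased_survey(
            cells, latent, effects, synthetic.default_selection_weights(cells),
            n=2000, noise_sd=1.0, seed=4, intercept=3.5)
        spec = ResponseModelSpec(
            demographics=tuple(synthetic.DEMOGRAPHIC_LEVELS), chains=2,
            draws=300, warmup=300, seed=5)
        fit = smallarea.fit_response_model(survey, grid_5x5, None, spec)
        # effects are identified as within-factor contrasts; compare centered
        hits = total = 0
        for var, level_map in effects.items():
            levels = fit.meta["factors"][var]
            u = fit.stacked(f"u_{var}")
            u = u - u.mean(axis=1, keepdims=True)
            truth = np.array([level_map[l] for l in levels])
            truth = truth - truth.mean()
            post_mean, post_sd = u.mean(axis=0), u.std(axis=0, ddof=1)
            hits += int(np.sum(np.abs(post_mean - truth) <= 2 * post_sd))
            total += len(levels)
        assert hits >= 0.9 * total

    def test_null_spatial_signal_gives_low_mix(self, grid_5x5, national_joint):
        pops = {a: 2000 for a in grid_5x5.area_ids}
        cells = synthetic.make_population_cells(grid_5x5, national_joint, 300.0,
                                                pops, seed=6)
        latent, _ = synthetic.draw_latent_surface(grid_5x5, spatial_sd=0.0,
                                                  iid_sd=0.5, rho_mix=0.0, seed=7)
        survey, _ = synthetic.sample_biased_survey(
            cells, latent, None, None, n=2000, noise_sd=1.0, seed=8, intercept=3.5)
        spec = ResponseModelSpec(demographics=("gender",), chains=2, draws=300,
                                 warmup=300, seed=9)
        fit = smallarea.fit_response_model(survey, grid_5x5, None, spec)
        assert np.median(fit.stacked("spatial_mix")) < 0.5

    def test_missing_demographic_column_rejected(self, grid_3x3):
        survey = pd.DataFrame({"area_id": ["a0_0"] * 5,
                               "binding_score": np.zeros(5)})
        spec = ResponseModelSpec(demographics=("gender",), chains=2, draws=10,
                                 warmup=10)
        with pytest.raises(ValueError, match="gender"):
            smallarea.fit_response_model(survey, grid_3x3, None, spec)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            ResponseModelSpec(demographics=("gender",), chains=1)


# ---------------------------------------------------------------------------
# IPF
# ---------------------------------------------------------------------------

class TestIPF:
    def test_fixed_point_when_margins_match(self):
        idx = pd.MultiIndex.from_product([["a0", "a1"], ["b0", "b1", "b2"]],
                                         names=["A", "B"])
        joint = pd.Series([0.1, 0.2, 0.1, 0.25, 0.05, 0.3], index=idx)
        margins = {"x": {
            "A": joint.groupby(level="A").sum().to_dict(),
            "B": joint.groupby(level="B").sum().to_dict(),
        }}
        out = smallarea.synthesize_joint_ipf(margins, joint, tol=1e-12)
        assert np.abs(out["count"].to_numpy() - joint.to_numpy()).max() < 1e-9

    def test_uniform_seed_gives_independence_table(self):
        idx = pd.MultiIndex.from_product([["a0", "a1"], ["b0", "b1"]],
                                         names=["A", "B"])
        joint = pd.Series(0.25, index=idx)
        margins = {"x": {"A": {"a0": 0.6, "a1": 0.4},
                         "B": {"b0": 0.7, "b1": 0.3}}}
        out = smallarea.synthesize_joint_ipf(margins, joint, tol=1e-12)
        assert np.allclose(out["count"].to_numpy(),
                           [0.42, 0.18, 0.28, 0.12], atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_margins_reproduced(self, seed):
        rng = np.random.default_rng(seed)
        idx = pd.MultiIndex.from_product([["a", "b", "c"], ["x", "y"],
                                          ["u", "v", "w"]],
                                         names=["V1", "V2", "V3"])
        joint = pd.Series(rng.dirichlet(np.ones(len(idx))), index=idx)
        m1 = rng.dirichlet(np.ones(3)) * 1000
        m2 = rng.dirichlet(np.ones(2)) * 1000
        m3 = rng.dirichlet(np.ones(3)) * 1000
        margins = {"area": {"V1": dict(zip(["a", "b", "c"], m1)),
                            "V2": dict(zip(["x", "y"], m2)),
                            "V3": dict(zip(["u", "v", "w"], m3))}}
        out = smallarea.synthesize_joint_ipf(margins, joint, tol=1e-9)
        got = out.groupby("V1")["count"].sum()
        assert np.abs(got - pd.Series(dict(zip(["a", "b", "c"], m1)))).max() < 1e-5

    def test_inconsistent_totals_rejected(self):
        idx = pd.MultiIndex.from_product([["a0", "a1"], ["b0", "b1"]],
                                         names=["A", "B"])
        joint = pd.Series(0.25, index=idx)
        margins = {"x": {"A": {"a0": 60, "a1": 40},
                         "B": {"b0": 80, "b1": 40}}}
        with pytest.raises(ValueError, match="totals"):
            smallarea.synthesize_joint_ipf(margins, joint)

    def test_zero_support_cell_rejected(self):
        idx = pd.MultiIndex.from_product([["a0", "a1"], ["b0", "b1"]],
                                         names=["A", "B"])
        joint = pd.Series([0.5, 0.5, 0.0, 0.0], index=idx)  # no mass on a1
        margins = {"x": {"A": {"a0": 0.5, "a1": 0.5},
                         "B": {"b0": 0.5, "b1": 0.5}}}
        with pytest.raises(ValueError, match="zero-support"):
            smallarea.synthesize_joint_ipf(margins, joint)


# ---------------------------------------------------------------------------
# Prediction and poststratification
# ---------------------------------------------------------------------------

class TestPredictAndPoststratify:
    def test_zero_effects_predict_intercept(self):
        draws = make_smallarea_draws(["a", "b"], 1.5,
                                     {"gender": {"f": 0.0, "m": 0.0}})
        cells = pd.DataFrame({"area_id": ["a", "a", "b", "b"],
                              "gender": ["f", "m", "f", "m"],
                              "count": [1, 1, 1, 1]})
        preds = smallarea.predict_cells(draws, cells)
        assert np.allclose(preds, 1.5)

    def test_hand_computed_two_cells(self):
        draws = make_smallarea_draws(
            ["a", "b"], 1.0, {"gender": {"f": -0.2, "m": 0.2}},
            area_effect=np.array([0.5, -0.5]),
            region_codes=[0, 1], region_effect=np.array([0.1, -0.1]))
        cells = pd.DataFrame({"area_id": ["a", "b"], "gender": ["f", "m"],
                              "count": [1, 1]})
        preds = smallarea.predict_cells(draws, cells)
        # mu + u_gender + region + area effect, summed by hand
        assert np.allclose(preds[:, 0], 1.0 - 0.2 + 0.1 + 0.5)
        assert np.allclose(preds[:, 1], 1.0 + 0.2 - 0.1 - 0.5)

    def test_shape_contract(self):
        draws = make_smallarea_draws(["a"], 0.0, {"g": {"x": 0.1}}, n_draws=7,
                                     chains=2)
        cells = pd.DataFrame({"area_id": ["a"] * 3, "g": ["x"] * 3,
                              "count": [1, 2, 3]})
        assert smallarea.predict_cells(draws, cells).shape == (14, 3)

    def test_unseen_level_draws_from_pooled_prior(self):
        draws = make_smallarea_draws(["a"], 0.0, {"g": {"x": 0.3}},
                                     n_draws=2000, chains=2)
        cells = pd.DataFrame({"area_id": ["a", "a"], "g": ["x", "NEW"],
                              "count": [1, 1]})
        preds = smallarea.predict_cells(draws, cells, seed=1)
        assert np.allclose(preds[:, 0], 0.3)
        # pooled prior N(0, sd=1): mean near 0, spread near 1
        assert abs(preds[:, 1].mean()) < 0.1
        assert abs(preds[:, 1].std() - 1.0) < 0.1

    def test_uniform_counts_equal_unweighted_mean(self):
        preds = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
        cells = pd.DataFrame({"area_id": ["a"] * 3, "count": [5, 5, 5]})
        est, area_draws = smallarea.poststratify(preds, cells, return_draws=True)
        assert np.allclose(area_draws[:, 0], [2.0, 4.0])

    def test_two_cell_weighted_mean_toy(self):
        preds = np.array([[1.0, 2.0]])
        cells = pd.DataFrame({"area_id": ["a", "a"], "count": [300, 700]})
        est = smallarea.poststratify(preds, cells)
        assert np.isclose(est["mean"].iloc[0], 1.7)

    @settings(max_examples=25, deadline=None)
    @given(st.randoms(use_true_random=False))
    def test_permutation_invariance(self, rnd):
        rng = np.random.default_rng(rnd.randint(0, 2 ** 31))
        n_cells = 12
        preds = rng.normal(size=(9, n_cells))
        cells = pd.DataFrame({
            "area_id": rng.choice(["a", "b", "c"], n_cells),
            "count": rng.integers(1, 50, n_cells),
        })
        perm = rng.permutation(n_cells)
        est1 = smallarea.poststratify(preds, cells)
        est2 = smallarea.poststratify(preds[:, perm],
                                      cells.iloc[perm].reset_index(drop=True))
        assert np.allclose(est1["mean"].to_numpy(), est2["mean"].to_numpy(),
                           atol=1e-12)

    def test_zero_population_area_rejected(self):
        preds = np.zeros((3, 2))
        cells = pd.DataFrame({"area_id": ["a", "b"], "count": [10, 0]})
        with pytest.raises(ValueError, match="zero total population"):
            smallarea.poststratify(preds, cells)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

class TestValidation:
    def test_identical_gold(self):
        est = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        rep = smallarea.validate_against_gold(est, est)
        assert np.isclose(rep.r, 1.0) and np.isclose(rep.rmse, 0.0)
        assert rep.df == 2

    def test_anticorrelated_gold(self):
        est = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        rep = smallarea.validate_against_gold(est, -est)
        assert np.isclose(rep.r, -1.0)

    def test_five_point_toy_matches_brute_force(self):
        est = pd.Series([1.0, 2.0, 2.5, 4.0, 5.5], index=list("abcde"))
        gold = pd.Series([0.8, 2.4, 2.0, 4.4, 5.0], index=list("abcde"))
        rep = smallarea.validate_against_gold(est, gold)
        x, g = est.to_numpy(), gold.to_numpy()
        r_bf = (np.mean((x - x.mean()) * (g - g.mean()))
                / (x.std() * g.std()))
        rmse_bf = np.sqrt(np.mean((x - g) ** 2))
        assert np.isclose(rep.r, r_bf)
        assert np.isclose(rep.rmse, rmse_bf)
        assert np.isclose(rep.t, rep.r * np.sqrt(rep.df) / np.sqrt(1 - rep.r ** 2))

    def test_constant_estimates_rejected(self):
        est = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        gold = pd.Series([0.0, 1.0, 2.0], index=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            smallarea.validate_against_gold(est, gold)

    def test_insufficient_overlap_rejected(self):
        est = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError, match="overlap"):
            smallarea.validate_against_gold(est, est)
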