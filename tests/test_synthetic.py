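"""Generators: geography, populations, latent surfaces, surveys, counts,
experiments — determinism, conservation, and calibration checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ebep import synthetic
from conftest import brute_force_moran


class TestLatticeGeography:
    def test_degenerate_single_cell(self):
        g = synthetic.make_lattice_geography(1, 1, 1)
        assert g.n_areas == 1 and len(g.edges) == 0

    def test_rook_edge_count_3x3(self):
        # brute-force rook pairs on a 3x3 grid: 2 per row x 3 rows, twice
        g = synthetic.make_lattice_geography(3, 3, 1)
        assert len(g.edges) == 12

    def test_regions_cover_all_areas(self):
        g = synthetic.make_lattice_geography(10, 10, 4)
        assert set(g.region_of) == set(g.area_ids)
        assert len(set(g.region_of.values())) == 4
        a = g.adjacency_matrix()
        assert np.allclose(a, a.T) and np.all(np.diag(a) == 0)

    @pytest.mark.parametrize("rows,cols,regions", [(0, 3, 1), (3, 0, 1), (2, 2, 5)])
    def test_invalid_dimensions_rejected(self, rows, cols, regions):
        with pytest.raises(ValueError):
            synthetic.make_lattice_geography(rows, cols, regions)


class TestPopulationCells:
    def test_full_cell_product(self, grid_3x3, national_joint):
        pops = {a: 5000 for a in grid_3x3.area_ids}
        cells = synthetic.make_population_cells(grid_3x3, national_joint, 50.0,
                                                pops, seed=1)
        # 2*3*4*3*3*3 = 648 cells per area
        assert (cells.groupby("area_id").size() == 648).all()

    def test_population_conserved(self, grid_3x3, national_joint):
        pops = {a: 1234 + 17 * i for i, a in enumerate(grid_3x3.area_ids)}
        cells = synthetic.make_population_cells(grid_3x3, national_joint, 5.0,
                                                pops, seed=2)
        sums = cells.groupby("area_id")["count"].sum()
        for a, p in pops.items():
            assert sums[a] == p

    def test_infinite_concentration_matches_national_joint(self, grid_3x3,
                                                           national_joint):
        pops = {a: 100_000 for a in grid_3x3.area_ids}
        cells = synthetic.make_population_cells(grid_3x3, national_joint,
                                                np.inf, pops, seed=3)
        one = cells[cells["area_id"] == grid_3x3.area_ids[0]]
        shares = one["count"].to_numpy() / 100_000
        assert np.abs(shares - national_joint.to_numpy()).max() < 1e-5

    def test_unnormalized_joint_rejected(self, grid_3x3, national_joint):
        with pytest.raises(ValueError):
            synthetic.make_population_cells(grid_3x3, national_joint * 2, 5.0,
                                            {a: 100 for a in grid_3x3.area_ids})


class TestLatentSurface:
    def test_zero_spatial_sd_gives_iid_surface(self, grid_5x5):
        _, truth = synthetic.draw_latent_surface(grid_5x5, spatial_sd=0.0,
                                                 iid_sd=1.0, rho_mix=0.5, seed=4)
        assert all(v == 0.0 for v in truth.latent_spatial.values())

    def test_pure_spatial_sums_to_zero(self, grid_5x5):
        lat, _ = synthetic.draw_latent_surface(grid_5x5, spatial_sd=1.0,
                                               iid_sd=1.0, rho_mix=1.0, seed=5)
        assert abs(lat.to_numpy().mean()) < 1e-9

    def test_spatial_surface_has_positive_moran_i(self, grid_5x5):
        a = grid_5x5.adjacency_matrix()
        hits = 0
        for seed in range(100):
            lat, _ = synthetic.draw_latent_surface(grid_5x5, spatial_sd=2.0,
                                                   iid_sd=0.2, rho_mix=0.9,
                                                   seed=seed)
            hits += brute_force_moran(lat.to_numpy(), a) > 0
        assert hits >= 95

    def test_invalid_mix_rejected(self, grid_5x5):
        with pytest.raises(ValueError):
            synthetic.draw_latent_surface(grid_5x5, rho_mix=1.5)


@pytest.fixture(scope="module")
def frame(grid_3x3, national_joint):
    pops = {a: 10_000 for a in grid_3x3.area_ids}
    return synthetic.make_population_cells(grid_3x3, national_joint, np.inf,
                                           pops, seed=6)


class TestBiasedSurvey:
    def test_uniform_weights_representative(self, frame, grid_3x3):
        zeros = pd.Series(0.0, index=list(grid_3x3.area_ids))
        sv, _ = synthetic.sample_biased_survey(frame, zeros, None, None,
                                               n=30_000, seed=7)
        obs = sv["ideology"].value_counts()
        pop = frame.groupby("ideology")["count"].sum()
        pop_shares = pop / pop.sum()
        expected = pop_shares.reindex(obs.index) * len(sv)
        chi2 = ((obs - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=len(obs) - 1)
        assert p > 1e-3

    def test_heavy_bias_overrepresents_level(self, frame, grid_3x3):
        zeros = pd.Series(0.0, index=list(grid_3x3.area_ids))
        w = np.where(frame["ideology"] == "conservative", 10.0, 1.0)
        sv, _ = synthetic.sample_biased_survey(frame, zeros, None, w,
                                               n=20_000, seed=8)
        obs_share = (sv["ideology"] == "conservative").mean()
        pop = frame.groupby("ideology")["count"].sum()
        assert obs_share > 1.5 * pop["conservative"] / pop.sum()

    def test_noiseless_outcome_is_intercept_plus_latent(self, frame, grid_3x3):
        lat = pd.Series(np.linspace(-1, 1, grid_3x3.n_areas),
                        index=list(grid_3x3.area_ids))
        sv, _ = synthetic.sample_biased_survey(frame, lat, None, None, n=500,
                                               noise_sd=0.0, seed=9,
                                               intercept=2.0)
        expected = 2.0 + sv["area_id"].map(lat)
        assert np.allclose(sv["binding_score"], expected)

    def test_without_replacement_capacity(self, frame, grid_3x3):
        zeros = pd.Series(0.0, index=list(grid_3x3.area_ids))
        with pytest.raises(ValueError):
            synthetic.sample_biased_survey(frame, zeros, None, None,
                                           n=10_000_000, replace=False)

    def test_determinism(self, frame, grid_3x3):
        zeros = pd.Series(0.0, index=list(grid_3x3.area_ids))
        a, _ = synthetic.sample_biased_survey(frame, zeros, None, None, n=200,
                                              seed=10)
        b, _ = synthetic.sample_biased_survey(frame, zeros, None, None, n=200,
                                              seed=10)
        pd.testing.assert_frame_equal(a, b)


class TestAreaCounts:
    def test_mean_matches_intercept(self):
        # moment oracle on 10,000 areas: coefficients 0, exposure 1
        g = synthetic.make_lattice_geography(100, 100, 1)
        expos = pd.Series(1.0, index=list(g.area_ids))
        counts, _ = synthetic.draw_area_counts(
            g, pd.DataFrame(index=list(g.area_ids)), {"intercept": 0.5},
            None, dispersion=2.0, exposures=expos, seed=11)
        mu = np.exp(0.5)
        se = np.sqrt((mu + mu ** 2 / 2.0) / g.n_areas)
        assert abs(counts["count"].mean() - mu) < 4 * se

    def test_poisson_limit(self, grid_5x5):
        g = synthetic.make_lattice_geography(60, 60, 1)
        expos = pd.Series(1.0, index=list(g.area_ids))
        counts, _ = synthetic.draw_area_counts(
            g, pd.DataFrame(index=list(g.area_ids)), {"intercept": 1.0},
            None, dispersion=np.inf, exposures=expos, seed=12)
        ratio = counts["count"].var() / counts["count"].mean()
        assert 0.9 < ratio < 1.1

    def test_zero_exposure_rejected(self, grid_3x3):
        expos = pd.Series(0.0, index=list(grid_3x3.area_ids))
        with pytest.raises(ValueError):
            synthetic.draw_area_counts(grid_3x3,
                                       pd.DataFrame(index=list(grid_3x3.area_ids)),
                                       {"intercept": 0.0}, None, 1.0, expos)


class TestExperimentGenerator:
    def test_four_rows_per_participant_and_valid_responses(self):
        data, _ = synthetic.make_experiment_data(90, design="3-arm", seed=13)
        assert (data.groupby("participant_id").size() == 4).all()
        assert data["response"].between(1, 7).all()
        assert set(data["condition"]) == {"control", "binding", "individualizing"}

    def test_null_design_arms_indistinguishable(self):
        paths = synthetic.MediationPaths(
            a={"control": 0.0, "violation": 0.0}, a_binding=0.0, b=0.0,
            b_binding=0.0, b_individualizing=0.0,
            cprime={"control": 0.0, "violation": 0.0})
        data, _ = synthetic.make_experiment_data(4000, design="2-arm",
                                                 paths=paths, seed=14)
        tab = pd.crosstab(data["condition"], data["response"])
        chi2, p = stats.chi2_contingency(tab)[:2]
        assert p > 1e-3

    def test_large_b_gives_monotone_response_in_pmw_tertile(self):
        paths = synthetic.MediationPaths(b=2.0)
        data, _ = synthetic.make_experiment_data(3000, design="2-arm",
                                                 paths=paths, seed=15)
        tert = pd.qcut(data["pmw_z"], 3, labels=[0, 1, 2])
        means = data.groupby(tert, observed=True)["response"].mean()
        assert means.iloc[0] < means.iloc[1] < means.iloc[2]

    def test_reference_pmw_means_by_condition(self):
        # generator calibration target: control ~2.15, violations ~5.55 / 5.48
        data, _ = synthetic.make_experiment_data(9000, design="3-arm", seed=16)
        means = (data.drop_duplicates("participant_id")
                 .groupby("condition")["pmw"].mean())
        assert abs(means["control"] - 2.15) < 0.15
        assert abs(means["binding"] - 5.55) < 0.15
        assert abs(means["individualizing"] - 5.48) < 0.15

    def test_right_skewed_justification_responses(self):
        data, _ = synthetic.make_experiment_data(3000, design="3-arm", seed=17)
        control = data[data["condition"] == "control"]
        assert control.groupby("item_id")["response"].median().max() <= 2

    def test_nonincreasing_cutpoints_rejected(self):
        with pytest.raises(ValueError):
            synthetic.make_experiment_data(60, cutpoints=(1, 2, 2, 3, 4, 5))

    def test_determinism(self):
        a, ta = synthetic.make_experiment_data(60, seed=18)
        b, tb = synthetic.make_experiment_data(60, seed=18)
        pd.testing.assert_frame_equal(a, b)
        assert ta.to_dict() == tb.to_dict()
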