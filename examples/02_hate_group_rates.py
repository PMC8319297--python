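"""Spatially filtered negative-binomial regression of area hate-group rates.

Simulates 200 areas where one additional standard deviation of binding
values multiplies the hate-group rate per 10,000 inhabitants by 1.3, on top
of a smooth spatial nuisance field. The Moran-eigenvector filter absorbs the
residual spatial autocorrelation; the maximum-likelihood fixed-effects
contrast illustrates how region dummies attenuate a region-confounded
coefficient and inflate its standard error.
"""

import numpy as np
import pandas as pd

from ebep import spatial_count, synthetic

graph = synthetic.make_lattice_geography(20, 10, 5)
rng = np.random.default_rng(1)
covariates = pd.DataFrame({"binding": rng.normal(size=200),
                           "poverty": rng.normal(size=200)},
                          index=list(graph.area_ids))
latent, _ = synthetic.draw_latent_surface(graph, spatial_sd=0.4, iid_sd=0.0,
                                          rho_mix=1.0, seed=2)
counts, truth = synthetic.draw_area_counts(
    graph, covariates,
    {"intercept": -0.5, "binding": np.log(1.3), "poverty": 0.1},
    latent, dispersion=2.0,
    exposures=pd.Series(2.0, index=list(graph.area_ids)), seed=3)
print(f"simulated counts: mean {counts['count'].mean():.2f}, true binding "
      f"rate ratio {np.exp(truth.count_coefficients['binding']):.2f}")

basis = spatial_count.moran_eigenvector_basis(
    graph, spatial_count.default_basis_size(graph))
fit = spatial_count.fit_nb_spatial_filter(
    counts, covariates, basis,
    spatial_count.NBSpec(chains=2, draws=400, warmup=400, seed=4))
print("\nposterior rate ratios (per SD of the covariate):")
print(spatial_count.summarize_rate_ratios(fit).round(3).to_string(index=False))

fe = spatial_count.fit_nb_fixed_effects(
    counts, covariates, {a: graph.region_of[a] for a in graph.area_ids},
    include_fe=True)
no_fe = spatial_count.fit_nb_fixed_effects(counts, covariates, None)
b_fe = fe.loc[fe.term == "binding"].iloc[0]
b_no = no_fe.loc[no_fe.term == "binding"].iloc[0]
print(f"\nML contrast: binding coef {b_no['coef']:.3f} (se {b_no['se']:.3f}) "
      f"without region dummies vs {b_fe['coef']:.3f} (se {b_fe['se']:.3f}) with")
print("-> the interval for the binding ratio should cover 1.3; the "
      "fixed-effects fit identifies the effect from within-region variance "
      "only.")
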