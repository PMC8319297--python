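"""Small-area estimation of moral values from a biased opt-in survey.

Simulates a 5x5 county lattice with a spatially autocorrelated latent
binding-values surface, draws a non-representative survey (liberal and
college-educated respondents heavily overrepresented), fits the multilevel
response model with ICAR spatial smoothing, and poststratifies against the
population cell counts. The validation report compares the estimates with
the known truth — the poststratified estimates remove most of the selection
bias that distorts the raw area means.
"""

import numpy as np
import pandas as pd

from ebep import smallarea, synthetic

graph = synthetic.make_lattice_geography(5, 5, 3)
joint = synthetic.default_national_joint(seed=0)
cells = synthetic.make_population_cells(
    graph, joint, concentration=300.0,
    populations={a: 2000 for a in graph.area_ids}, seed=1)
latent, truth = synthetic.draw_latent_surface(
    graph, spatial_sd=0.5, iid_sd=0.15, rho_mix=0.85, seed=2)
effects = {"ideology": {"liberal": -0.6, "moderate": 0.0, "conservative": 0.6},
           "attendance": {"never": -0.2, "sometimes": 0.0, "weekly": 0.3}}
survey, _ = synthetic.sample_biased_survey(
    cells, latent, effects, synthetic.default_selection_weights(cells),
    n=2000, noise_sd=1.0, seed=3, intercept=3.5)

spec = smallarea.ResponseModelSpec(
    demographics=tuple(synthetic.DEMOGRAPHIC_LEVELS),
    chains=2, draws=300, warmup=300, seed=4)
fit = smallarea.fit_response_model(survey, graph, None, spec)
print(f"sampler max split R-hat: {fit.diagnostics['max_rhat']:.3f}")

preds = smallarea.predict_cells(fit, cells, seed=5)
estimates = smallarea.poststratify(preds, cells)
print(estimates.head().to_string(index=False))

truth_area = pd.Series(truth.latent_total) + 3.5
report = smallarea.validate_against_gold(estimates, truth_area)
raw = survey.groupby("area_id")["binding_score"].mean()
raw_mae = (raw.reindex(truth_area.index) - truth_area).abs().mean()
mrp_mae = (estimates.set_index("area_id")["mean"].reindex(truth_area.index)
           - truth_area).abs().mean()
print(f"\nvalidation vs truth: r({report.df}) = {report.r:.2f}, "
      f"t = {report.t:.2f}, RMSE = {report.rmse:.3f}")
print(f"mean absolute error: poststratified {mrp_mae:.3f} vs raw means "
      f"{raw_mae:.3f}")
print("-> the model-based estimates track the latent surface closely; the "
      "raw means carry the opt-in selection bias.")
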