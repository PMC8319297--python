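"""Posterior-simulation mediation: condition -> PMW -> justification.

Designed simulation with a pure indirect path: the vignette manipulation
raises perceived moral wrongness (a > 0), PMW raises justification
(b > 0), and there is no direct effect (c' = 0). The ACME interval should
exclude zero while the ADE interval covers zero, and each posterior draw
decomposes exactly as total = ACME + ADE.
"""

import numpy as np

from ebep import mediation, ordinal, synthetic

paths = synthetic.MediationPaths(
    a={"control": 0.0, "violation": 3.4},
    cprime={"control": 0.0, "violation": 0.0}, b=1.2)
data, _ = synthetic.make_experiment_data(300, design="2-arm", paths=paths,
                                         seed=1)
participants = data.drop_duplicates("participant_id").reset_index(drop=True)

med_fit = mediation.fit_mediator(
    participants, ("treat", "binding_z", "individualizing_z"),
    chains=2, draws=300, seed=2)
spec = ordinal.OrdinalModelSpec(
    fixed_terms=("treat", "binding_z", "individualizing_z", "pmw_z"),
    item_slope_terms=("pmw_z",), chains=2, draws=300, warmup=300, seed=3)
out_fit = ordinal.fit_cumulative_model(data, spec)

effects = mediation.estimate_mediation_effects(
    med_fit, out_fit, data, threshold=2, n_sims=100, seed=4)
print(f"outcome scale: {effects.outcome_scale}")
for name, s in (("ACME", effects.acme), ("ADE", effects.ade),
                ("total", effects.total)):
    print(f"{name:>6}: {s['mean']:.3f} [{s['q2.5']:.3f}, {s['q97.5']:.3f}]")
print(f"proportion mediated: {effects.proportion_mediated['mean']:.2f}")
dev = np.abs(effects.draws["total"]
             - (effects.draws["acme"] + effects.draws["ade"])).max()
print(f"max |total - (ACME + ADE)| over draws: {dev:.2e}")
print("-> the manipulation changes justification only through perceived "
      "moral wrongness; the direct path is indistinguishable from zero.")
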