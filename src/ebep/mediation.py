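"""Posterior-simulation causal mediation with an ordinal outcome.

The mediator model is a Gaussian linear regression of (z-scored) perceived
moral wrongness on treatment, moral values, their interactions, and
covariates; the outcome model is the hierarchical cumulative-logit model of
EBEP justification. For each posterior draw s, counterfactual mediator
values M_i(t) are simulated for every observed covariate profile i from the
mediator's posterior predictive, and the outcome scale is the probability
of responding at least at a threshold category ("at least slightly
justified" = response >= 2), marginalized across the four items and over
the participant-intercept distribution. Effects per draw:

``ACME(t) = mean_i[ p(t, M_i(1)) - p(t, M_i(0)) ]``
``ADE(t)  = mean_i[ p(1, M_i(t)) - p(0, M_i(t)) ]``

with reported ACME = (ACME(0)+ACME(1))/2, ADE likewise, and total = ACME +
ADE exactly per draw (both average the same simulated units). Moderated
mediation recomputes everything with a moderator pinned at -1 and +1 SD in
both models simultaneously and contrasts the two ACMEs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ebep.ordinal import design_matrix
from ebep.samplers import sample_linear_model
from ebep.types import PosteriorDraws, summarize_draws


# ---------------------------------------------------------------------------
# Mediator model
# ---------------------------------------------------------------------------

def fit_mediator(
    data: pd.DataFrame,
    terms: Sequence[str],
    response: str = "pmw_z",
    chains: int = 2,
    draws: int = 500,
    seed: int = 0,
) -> PosteriorDraws:
    """Bayesian linear regression of the mediator on the named terms.

    Conjugate under the reference prior, so the posterior is sampled
    exactly (no MCMC error beyond the draws themselves). ``data`` should be
    one row per participant.
    """
    x = np.column_stack([np.ones(len(data)), design_matrix(data, terms)])
    y = data[response].to_numpy(dtype=float)
    beta, sigma = sample_linear_model(x, y, chains, draws, seed)
    out = {"intercept": beta[:, :, 0], "sigma": sigma}
    for j, t in enumerate(terms):
        out[f"b_{t}"] = beta[:, :, j + 1]
    meta = {"model": "mediator_lm", "terms": list(terms), "response": response}
    return PosteriorDraws(out, meta=meta)


def _mediator_eta(mediator_draws: PosteriorDraws, df: pd.DataFrame) -> np.ndarray:
    """Linear predictor (S, n) of the mediator model at the given frame."""
    terms = mediator_draws.meta["terms"]
    x = np.column_stack([np.ones(len(df)), design_matrix(df, terms)])
    beta = np.column_stack(
        [mediator_draws.stacked("intercept")]
        + [mediator_draws.stacked(f"b_{t}") for t in terms])
    return beta @ x.T


def simulate_counterfactual_mediator(
    mediator_draws: PosteriorDraws,
    profiles: pd.DataFrame,
    treatment_value: float,
    moderator: str | None = None,
    moderator_value: float | None = None,
    seed: int = 0,
    noise: np.ndarray | None = None,
    treatment_col: str = "treat",
) -> np.ndarray:
    """Posterior-predictive mediator values at a set treatment level.

    Returns an (S, n_profiles) array: linear predictor plus residual noise.
    ``noise`` (standard-normal, same shape) may be supplied to share
    residual draws across counterfactual treatment levels.
    """
    df = profiles.copy()
    df[treatment_col] = treatment_value
    if moderator is not None:
        if moderator_value is None:
            raise ValueError("moderator named but no value supplied")
        df[moderator] = moderator_value
    eta = _mediator_eta(mediator_draws, df)
    sigma = mediator_draws.stacked("sigma")
    if noise is None:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(eta.shape)
    elif noise.shape != eta.shape:
        raise ValueError("noise shape mismatch")
    return eta + sigma[:, None] * noise


# ---------------------------------------------------------------------------
# Outcome-scale machinery
# ---------------------------------------------------------------------------

def _outcome_eta_components(
    outcome_draws: PosteriorDraws,
    profiles: pd.DataFrame,
    treatment_col: str,
    treatment_value: float,
    mediator_col: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Decompose the outcome linear predictor as A + B * m.

    Every model term is a product of columns, so the predictor is linear in
    the mediator column; A and B have shape (S, n_profiles, n_items).
    """
    meta = outcome_draws.meta
    df0 = profiles.copy()
    df0[treatment_col] = treatment_value
    df0[mediator_col] = 0.0
    df1 = df0.copy()
    df1[mediator_col] = 1.0
    terms = meta["fixed_terms"]
    x0 = design_matrix(df0, terms)
    x1 = design_matrix(df1, terms)
    beta = (np.column_stack([outcome_draws.stacked(f"b_{t}") for t in terms])
            if terms else np.zeros((outcome_draws.stacked("cutpoints").shape[0], 0)))
    a_fixed = beta @ x0.T  # (S, n)
    b_fixed = beta @ (x1 - x0).T
    item_eff = outcome_draws.stacked("item_effect")  # (S, J)
    a = a_fixed[:, :, None] + item_eff[:, None, :]
    b = np.repeat(b_fixed[:, :, None], item_eff.shape[1], axis=2)
    for t in meta["item_slope_terms"]:
        sl = outcome_draws.stacked(f"item_slope_{t}")  # (S, J)
        col0 = design_matrix(df0, [t]).ravel()
        col1 = design_matrix(df1, [t]).ravel()
        a = a + sl[:, None, :] * col0[None, :, None]
        b = b + sl[:, None, :] * (col1 - col0)[None, :, None]
    return a, b


def _mean_exceedance(a: np.ndarray, b: np.ndarray, m: np.ndarray,
                     cuts: np.ndarray, sd_p: np.ndarray, threshold: int,
                     z: np.ndarray) -> np.ndarray:
    """Per-draw P(Y >= threshold) averaged over items and units, with the
    participant intercept integrated over the supplied standard-normal
    nodes. a, b: (S, n, J); m: (S, n); cuts: (S, 6); sd_p: (S,)."""
    eta = a + b * m[:, :, None]  # (S, n, J)
    x = eta - cuts[:, int(threshold) - 2][:, None, None]
    acc = np.zeros(x.shape[:2])
    for zz in z:
        acc += expit(x + (sd_p * zz)[:, None, None]).mean(axis=2)
    return (acc / len(z)).mean(axis=1)


# ---------------------------------------------------------------------------
# Effects
# ---------------------------------------------------------------------------

@dataclass
class MediationEffects:
    """ACME/ADE/total-effect summaries with per-draw arrays.

    All effects are on the declared outcome scale: the probability of a
    response at or above the threshold category, marginalized over items
    and participant effects.
    """

    acme: dict
    ade: dict
    total: dict
    proportion_mediated: dict
    outcome_scale: str
    draws: dict

    def to_dict(self) -> dict:
        return {"acme": self.acme, "ade": self.ade, "total": self.total,
                "proportion_mediated": self.proportion_mediated,
                "outcome_scale": self.outcome_scale}


def estimate_mediation_effects(
    mediator_draws: PosteriorDraws,
    outcome_draws: PosteriorDraws,
    data: pd.DataFrame,
    threshold: int = 2,
    n_sims: int = 100,
    seed: int = 0,
    treatment_col: str = "treat",
    treat_values: tuple[float, float] = (0.0, 1.0),
    mediator_col: str = "pmw_z",
    moderator: str | None = None,
    moderator_value: float | None = None,
    participant_col: str = "participant_id",
    scale: str = "probability",
) -> MediationEffects:
    """Average causal mediation effect, direct effect, and total effect.

    Counterfactual units are the observed participant covariate profiles.
    ``n_sims`` controls the Monte Carlo integration over the participant
    intercept; mediator residual noise is shared across treatment levels
    (common random numbers), which leaves each draw's ACME + ADE = total
    decomposition exact.

    ``scale="probability"`` (default) reports effects as changes in
    P(response >= threshold); ``scale="latent"`` reports them on the latent
    justification scale (mean linear predictor, items averaged), where a
    model with no interactions reduces ACME to the product of coefficients.
    """
    if scale not in ("probability", "latent"):
        raise ValueError("scale must be 'probability' or 'latent'")
    if not any(mediator_col in t.split(":") for t in outcome_draws.meta["fixed_terms"]):
        raise ValueError(f"outcome model does not contain the mediator "
                         f"{mediator_col!r}")
    if not (2 <= int(threshold) <= 7):
        raise ValueError("threshold must be between 2 and 7")
    profiles = data.drop_duplicates(subset=participant_col).reset_index(drop=True)
    if moderator is not None:
        profiles = profiles.copy()
        profiles[moderator] = moderator_value
    rng = np.random.default_rng(seed)
    s = mediator_draws.stacked("intercept").shape[0]
    s_out = outcome_draws.stacked("cutpoints").shape[0]
    if s != s_out:
        raise ValueError("mediator and outcome fits must have the same number "
                         f"of posterior draws (got {s} and {s_out})")
    n = len(profiles)
    eps = rng.standard_normal((s, n))
    t0, t1 = treat_values
    m0 = simulate_counterfactual_mediator(
        mediator_draws, profiles, t0, moderator, moderator_value,
        noise=eps, treatment_col=treatment_col)
    m1 = simulate_counterfactual_mediator(
        mediator_draws, profiles, t1, moderator, moderator_value,
        noise=eps, treatment_col=treatment_col)

    cuts = outcome_draws.stacked("cutpoints")
    sd_p = outcome_draws.stacked("sd_participant")
    z = rng.standard_normal(n_sims)
    p = {}
    for t_lab, t_val in (("0", t0), ("1", t1)):
        a, b = _outcome_eta_components(outcome_draws, profiles, treatment_col,
                                       t_val, mediator_col)
        for m_lab, m in (("0", m0), ("1", m1)):
            if scale == "probability":
                p[(t_lab, m_lab)] = _mean_exceedance(a, b, m, cuts, sd_p,
                                                     threshold, z)
            else:
                p[(t_lab, m_lab)] = (a + b * m[:, :, None]).mean(axis=(1, 2))
    acme0 = p[("0", "1")] - p[("0", "0")]
    acme1 = p[("1", "1")] - p[("1", "0")]
    ade0 = p[("1", "0")] - p[("0", "0")]
    ade1 = p[("1", "1")] - p[("0", "1")]
    acme = 0.5 * (acme0 + acme1)
    ade = 0.5 * (ade0 + ade1)
    total = p[("1", "1")] - p[("0", "0")]
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = np.where(np.abs(total) > 1e-12, acme / total, np.nan)
    scale_label = (f"P(response >= {int(threshold)}), marginalized over items"
                   if scale == "probability" else
                   "latent justification scale (items averaged)")
    return MediationEffects(
        acme=summarize_draws(acme),
        ade=summarize_draws(ade),
        total=summarize_draws(total),
        proportion_mediated=(summarize_draws(prop[np.isfinite(prop)])
                             if np.any(np.isfinite(prop)) else
                             {"mean": float("nan"), "sd": float("nan"),
                              "q2.5": float("nan"), "q97.5": float("nan")}),
        outcome_scale=scale_label,
        draws={"acme": acme, "ade": ade, "total": total,
               "proportion_mediated": prop},
    )


@dataclass
class ModeratedMediationEffects:
    """Mediation effects with a moderator pinned at low (-1 SD) and high
    (+1 SD) values, plus the high-minus-low ACME contrast."""

    low: MediationEffects
    high: MediationEffects
    acme_contrast: dict
    moderator: str
    levels: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "moderator": self.moderator,
            "levels": list(self.levels),
            "low": self.low.to_dict(),
            "high": self.high.to_dict(),
            "acme_contrast_high_minus_low": self.acme_contrast,
        }


def moderated_mediation_grid(
    mediator_draws: PosteriorDraws,
    outcome_draws: PosteriorDraws,
    data: pd.DataFrame,
    moderator: str,
    levels: tuple[float, float] = (-1.0, 1.0),
    threshold: int = 2,
    n_sims: int = 100,
    seed: int = 0,
    **kwargs,
) -> ModeratedMediationEffects:
    """Mediation effects at moderator = -1 SD and +1 SD (z scale).

    The moderator must interact with treatment and/or the mediator in at
    least one model; both levels are computed from the same posterior draws
    and the same simulated noise, so the high-minus-low ACME contrast has a
    per-draw interval.
    """
    in_mediator = any(moderator in t.split(":") and ":" in t
                      for t in mediator_draws.meta["terms"])
    in_outcome = any(moderator in t.split(":") and ":" in t
                     for t in outcome_draws.meta["fixed_terms"])
    if not (in_mediator or in_outcome):
        raise ValueError(f"{moderator!r} does not interact with any model term")
    lo_val, hi_val = levels
    low = estimate_mediation_effects(
        mediator_draws, outcome_draws, data, threshold=threshold,
        n_sims=n_sims, seed=seed, moderator=moderator,
        moderator_value=lo_val, **kwargs)
    high = estimate_mediation_effects(
        mediator_draws, outcome_draws, data, threshold=threshold,
        n_sims=n_sims, seed=seed, moderator=moderator,
        moderator_value=hi_val, **kwargs)
    contrast = high.draws["acme"] - low.draws["acme"]
    return ModeratedMediationEffects(
        low=low,
        high=high,
        acme_contrast=summarize_draws(contrast),
        moderator=moderator,
        levels=(float(lo_val), float(hi_val)),
    )
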