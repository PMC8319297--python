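"""Hierarchical Bayesian cumulative-logit models for ordinal EBEP items.

Four justification items (7-point, 1 = "not at all justified") are modeled
jointly with crossed random effects: a varying intercept per participant, a
varying intercept per item, and optionally item-varying slopes for selected
terms (e.g., the effect of experimental condition or of perceived moral
wrongness differs between posting hate speech and physical assault).

``P(Y <= k | eta) = logistic(c_k - eta)`` with six ordered cutpoints
(parameterized as a free first cutpoint plus positive log-gaps, so ordering
holds by construction) and

``eta = x' beta + sigma_p z_p[participant] + sigma_i z_i[item]
        + sum_t sigma_t z_t[item] * x_t``

All random effects are non-centered standard normals scaled by half-normal
standard deviations. The model is fit with the in-package NUTS sampler
using analytic gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy import stats

from ebep.samplers import run_nuts_chains
from ebep.types import PosteriorDraws

N_CATEGORIES = 7


@dataclass
class OrdinalModelSpec:
    """Terms and sampler settings for the cumulative-logit model.

    ``fixed_terms`` are column names of the experiment table; a term
    ``"a:b"`` denotes the elementwise product. ``item_slope_terms`` get an
    item-varying slope in addition to (any) fixed effect.
    """

    fixed_terms: tuple[str, ...]
    item_slope_terms: tuple[str, ...] = ()
    response: str = "response"
    participant: str = "participant_id"
    item: str = "item_id"
    chains: int = 2
    draws: int = 400
    warmup: int = 400
    seed: int = 0
    target_accept: float = 0.9
    max_depth: int = 8
    prior_scales: dict = field(default_factory=lambda: {
        "beta": 5.0, "sd": 2.0, "cut": 5.0, "log_gap": 1.5})


def design_matrix(data: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    """Column-stack the named terms; ``a:b`` builds the product column."""
    cols = []
    for t in terms:
        if ":" in t:
            parts = t.split(":")
            col = np.ones(len(data))
            for pcol in parts:
                col = col * data[pcol].to_numpy(dtype=float)
        else:
            col = data[t].to_numpy(dtype=float)
        cols.append(col)
    if not cols:
        return np.zeros((len(data), 0))
    return np.column_stack(cols)


def _stable_interval_prob(upper: np.ndarray, lower: np.ndarray):
    """P = expit(upper) - expit(lower) with tail-stable evaluation, plus the
    logistic densities at both bounds (0 where the bound is infinite)."""
    f_up = np.where(np.isfinite(upper), expit(upper), 1.0)
    f_lo = np.where(np.isfinite(lower), expit(lower), 0.0)
    p = f_up - f_lo
    # in the far upper tail both expits saturate at 1; recompute from the
    # complementary side
    hi = (np.minimum(np.where(np.isfinite(upper), upper, np.inf),
                     np.where(np.isfinite(lower), lower, np.inf)) > 20)
    if np.any(hi):
        cu = np.where(np.isfinite(upper), expit(-upper), 0.0)
        cl = np.where(np.isfinite(lower), expit(-lower), 1.0)
        p = np.where(hi, cl - cu, p)
    p = np.maximum(p, 1e-300)
    d_up = np.where(np.isfinite(upper), f_up * (1.0 - f_up), 0.0)
    d_lo = np.where(np.isfinite(lower), f_lo * (1.0 - f_lo), 0.0)
    return p, d_up, d_lo


def fit_cumulative_model(data: pd.DataFrame, spec: OrdinalModelSpec) -> PosteriorDraws:
    """Fit the hierarchical cumulative-logit model by NUTS."""
    y = data[spec.response].to_numpy()
    if not np.all((y == np.rint(y)) & (y >= 1) & (y <= N_CATEGORIES)):
        raise ValueError(f"responses must be integers in 1..{N_CATEGORIES}")
    y = y.astype(int)
    pid_raw = data[spec.participant].to_numpy()
    iid_raw = data[spec.item].to_numpy()
    p_levels, pid = np.unique(pid_raw, return_inverse=True)
    i_levels, iid = np.unique(iid_raw, return_inverse=True)
    n_p, n_i = len(p_levels), len(i_levels)
    if n_p < 2 or n_i < 2:
        raise ValueError("need at least 2 participants and 2 items")
    x = design_matrix(data, spec.fixed_terms)
    p = x.shape[1]
    slope_cols = [design_matrix(data, [t]).ravel() for t in spec.item_slope_terms]
    n_slopes = len(slope_cols)
    n = len(y)

    ps = spec.prior_scales
    n_cut = N_CATEGORIES - 1
    # packing: c1, log_gaps(5), beta(p), log_sd_p, z_p(n_p), log_sd_i,
    # z_i(n_i), then per slope term: log_sd_t, z_t(n_i)
    dim = 1 + (n_cut - 1) + p + 1 + n_p + 1 + n_i + n_slopes * (1 + n_i)
    idx_gap = slice(1, n_cut)
    idx_beta = slice(n_cut, n_cut + p)
    i_lsp = n_cut + p
    idx_zp = slice(i_lsp + 1, i_lsp + 1 + n_p)
    i_lsi = i_lsp + 1 + n_p
    idx_zi = slice(i_lsi + 1, i_lsi + 1 + n_i)
    slope_idx = []
    pos = i_lsi + 1 + n_i
    for _ in range(n_slopes):
        slope_idx.append((pos, slice(pos + 1, pos + 1 + n_i)))
        pos += 1 + n_i

    y_up = y - 1      # cutpoint index of the upper bound (y<7)
    y_lo = y - 2      # cutpoint index of the lower bound (y>1)
    has_up = y < N_CATEGORIES
    has_lo = y > 1

    def logp_grad(th: np.ndarray) -> tuple[float, np.ndarray]:
        c1 = th[0]
        gaps = np.exp(th[idx_gap])
        cuts = c1 + np.concatenate([[0.0], np.cumsum(gaps)])
        beta = th[idx_beta]
        sd_p = np.exp(th[i_lsp])
        z_p = th[idx_zp]
        sd_i = np.exp(th[i_lsi])
        z_i = th[idx_zi]
        eta = (x @ beta if p else np.zeros(n)) + sd_p * z_p[pid] + sd_i * z_i[iid]
        sds_t, zs_t = [], []
        for t, (i_lst, idx_zt) in enumerate(slope_idx):
            sd_t = np.exp(th[i_lst])
            z_t = th[idx_zt]
            eta = eta + sd_t * z_t[iid] * slope_cols[t]
            sds_t.append(sd_t)
            zs_t.append(z_t)

        upper = np.where(has_up, cuts[np.minimum(y_up, n_cut - 1)] - eta, np.inf)
        lower = np.where(has_lo, cuts[np.maximum(y_lo, 0)] - eta, -np.inf)
        prob, d_up, d_lo = _stable_interval_prob(upper, lower)
        ll = float(np.log(prob).sum())

        w_up = d_up / prob
        w_lo = d_lo / prob
        deta = w_lo - w_up  # d ll / d eta per row

        g = np.zeros(dim)
        # cutpoints: d ll/d c_k = w_up at k=y-1 minus w_lo at k=y-2
        gc = (np.bincount(np.where(has_up, y_up, 0), weights=np.where(has_up, w_up, 0.0),
                          minlength=n_cut)
              - np.bincount(np.where(has_lo, y_lo, 0), weights=np.where(has_lo, w_lo, 0.0),
                            minlength=n_cut))
        g[0] = gc.sum() - c1 / ps["cut"] ** 2
        # log-gap m affects cutpoints j >= m+1
        tail = np.cumsum(gc[::-1])[::-1]
        g[idx_gap] = gaps * tail[1:] - th[idx_gap] / ps["log_gap"] ** 2
        lp = (ll - 0.5 * c1 ** 2 / ps["cut"] ** 2
              - 0.5 * float(th[idx_gap] @ th[idx_gap]) / ps["log_gap"] ** 2)
        if p:
            g[idx_beta] = x.T @ deta - beta / ps["beta"] ** 2
            lp += -0.5 * float(beta @ beta) / ps["beta"] ** 2
        # participant effects
        gzp = sd_p * np.bincount(pid, weights=deta, minlength=n_p) - z_p
        g[idx_zp] = gzp
        g[i_lsp] = sd_p * float(z_p[pid] @ deta) - sd_p ** 2 / ps["sd"] ** 2 + 1.0
        lp += (-0.5 * float(z_p @ z_p) - 0.5 * sd_p ** 2 / ps["sd"] ** 2 + th[i_lsp])
        # item intercepts
        gzi = sd_i * np.bincount(iid, weights=deta, minlength=n_i) - z_i
        g[idx_zi] = gzi
        g[i_lsi] = sd_i * float(z_i[iid] @ deta) - sd_i ** 2 / ps["sd"] ** 2 + 1.0
        lp += (-0.5 * float(z_i @ z_i) - 0.5 * sd_i ** 2 / ps["sd"] ** 2 + th[i_lsi])
        # item slopes
        for t, (i_lst, idx_zt) in enumerate(slope_idx):
            wd = deta * slope_cols[t]
            g[idx_zt] = sds_t[t] * np.bincount(iid, weights=wd, minlength=n_i) - zs_t[t]
            g[i_lst] = (sds_t[t] * float(zs_t[t][iid] @ wd)
                        - sds_t[t] ** 2 / ps["sd"] ** 2 + 1.0)
            lp += (-0.5 * float(zs_t[t] @ zs_t[t])
                   - 0.5 * sds_t[t] ** 2 / ps["sd"] ** 2 + th[i_lst])
        return lp, g

    # initialize cutpoints near the empirical cumulative logits
    cum = np.cumsum(np.bincount(y, minlength=N_CATEGORIES + 1)[1:]) / n
    cum = np.clip(cum[:n_cut], 0.01, 0.99)
    c_emp = np.log(cum / (1 - cum))
    c_emp = np.maximum.accumulate(c_emp + 1e-3 * np.arange(n_cut))

    def init(rng) -> np.ndarray:
        th = rng.normal(0, 0.1, size=dim)
        th[0] = c_emp[0] + rng.normal(0, 0.1)
        th[idx_gap] = np.log(np.maximum(np.diff(c_emp), 0.1)) + rng.normal(0, 0.1, n_cut - 1)
        th[i_lsp] = np.log(0.5)
        th[i_lsi] = np.log(0.5)
        for i_lst, _ in slope_idx:
            th[i_lst] = np.log(0.3)
        return th

    raw, info = run_nuts_chains(logp_grad, init, dim, spec.chains, spec.warmup,
                                spec.draws, spec.seed,
                                target_accept=spec.target_accept,
                                max_depth=spec.max_depth)
    c1 = raw[:, :, 0]
    gaps = np.exp(raw[:, :, idx_gap])
    cuts = c1[:, :, None] + np.concatenate(
        [np.zeros_like(c1)[:, :, None], np.cumsum(gaps, axis=2)], axis=2)
    draws: dict[str, np.ndarray] = {"cutpoints": cuts}
    for j, t in enumerate(spec.fixed_terms):
        draws[f"b_{t}"] = raw[:, :, n_cut + j]
    draws["sd_participant"] = np.exp(raw[:, :, i_lsp])
    draws["sd_item"] = np.exp(raw[:, :, i_lsi])
    draws["z_participant"] = raw[:, :, idx_zp]
    draws["item_effect"] = np.exp(raw[:, :, i_lsi])[:, :, None] * raw[:, :, idx_zi]
    for t, (i_lst, idx_zt) in enumerate(slope_idx):
        name = spec.item_slope_terms[t]
        draws[f"sd_item_slope_{name}"] = np.exp(raw[:, :, i_lst])
        draws[f"item_slope_{name}"] = (np.exp(raw[:, :, i_lst])[:, :, None]
                                       * raw[:, :, idx_zt])
    meta = {
        "model": "cumulative_logit",
        "fixed_terms": list(spec.fixed_terms),
        "item_slope_terms": list(spec.item_slope_terms),
        "items": [str(v) for v in i_levels],
        "n_participants": int(n_p),
        "response": spec.response,
    }
    fit = PosteriorDraws(draws, meta=meta)
    fit.diagnostics["divergences"] = info["divergences"]
    return fit


# ---------------------------------------------------------------------------
# Probability machinery
# ---------------------------------------------------------------------------

def _profile_eta(draws: PosteriorDraws, profiles: pd.DataFrame) -> np.ndarray:
    """Linear predictor per (draw, profile, item), excluding the participant
    effect. Item intercepts and item slopes are taken from their draws."""
    meta = draws.meta
    for t in meta["fixed_terms"]:
        for col in t.split(":"):
            if col not in profiles.columns:
                raise ValueError(f"profile missing term column {col!r}")
    x = design_matrix(profiles, meta["fixed_terms"])  # (n_prof, p)
    beta = np.column_stack([draws.stacked(f"b_{t}") for t in meta["fixed_terms"]]) \
        if meta["fixed_terms"] else np.zeros((draws.stacked("cutpoints").shape[0], 0))
    eta = beta @ x.T  # (S, n_prof)
    item_eff = draws.stacked("item_effect")  # (S, n_items)
    out = eta[:, :, None] + item_eff[:, None, :]
    for t in meta["item_slope_terms"]:
        col = design_matrix(profiles, [t]).ravel()  # (n_prof,)
        sl = draws.stacked(f"item_slope_{t}")  # (S, n_items)
        out = out + sl[:, None, :] * col[None, :, None]
    return out


def cumulative_category_probs(cutpoints: Sequence[float],
                              eta: float | np.ndarray) -> np.ndarray:
    """Category probabilities of a cumulative-logit model with arbitrary
    ordered cutpoints: P(Y = k) = logistic(c_k - eta) - logistic(c_{k-1} - eta).

    Works for any number of categories (len(cutpoints) + 1); the last axis
    of the result indexes categories.
    """
    c = np.asarray(cutpoints, dtype=float)
    if c.ndim != 1 or np.any(np.diff(c) <= 0):
        raise ValueError("cutpoints must be strictly increasing")
    eta = np.asarray(eta, dtype=float)
    cdf = expit(c - eta[..., None])
    ones = np.ones(eta.shape + (1,))
    return np.diff(np.concatenate([np.zeros_like(ones), cdf, ones], axis=-1), axis=-1)


def category_probabilities(
    draws: PosteriorDraws,
    profiles: pd.DataFrame,
    re_policy: str = "simulate",
    n_sims: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Per (draw, profile, item) probabilities of the 7 response categories.

    ``re_policy="simulate"`` integrates the participant intercept over fresh
    ``N(0, sd_participant)`` draws (population-level probabilities);
    ``"zero"`` conditions on a typical participant (intercept 0).
    """
    if re_policy not in ("simulate", "zero"):
        raise ValueError("re_policy must be 'simulate' or 'zero'")
    eta = _profile_eta(draws, profiles)  # (S, n_prof, n_items)
    cuts = draws.stacked("cutpoints")  # (S, 6)
    s, n_prof, n_items = eta.shape
    if re_policy == "zero":
        cdf = expit(cuts[:, None, None, :] - eta[:, :, :, None])
    else:
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n_sims)
        sd_p = draws.stacked("sd_participant")
        cdf = np.zeros((s, n_prof, n_items, N_CATEGORIES - 1))
        for zz in z:
            off = (sd_p * zz)[:, None, None, None]
            cdf += expit(cuts[:, None, None, :] - eta[:, :, :, None] - off)
        cdf /= n_sims
    cdf_full = np.concatenate(
        [np.zeros((s, n_prof, n_items, 1)), cdf, np.ones((s, n_prof, n_items, 1))],
        axis=3)
    probs = np.diff(cdf_full, axis=3)
    return probs


def exceedance_probability(
    draws: PosteriorDraws,
    profiles: pd.DataFrame,
    threshold: int,
    n_sims: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Per-draw P(response >= threshold), averaged over items, with the
    participant intercept integrated by simulation. Shape (S, n_profiles).

    ``threshold=2`` is the default mapping of "at least slightly justified"
    on the 1..7 scale.
    """
    if not (2 <= int(threshold) <= N_CATEGORIES):
        raise ValueError("threshold must be between 2 and 7")
    probs = category_probabilities(draws, profiles, re_policy="simulate",
                                   n_sims=n_sims, seed=seed)
    exceed = probs[:, :, :, int(threshold) - 1:].sum(axis=3)  # (S, prof, item)
    return exceed.mean(axis=2)


# ---------------------------------------------------------------------------
# Scale reliability
# ---------------------------------------------------------------------------

def cronbach_alpha(item_matrix: np.ndarray | pd.DataFrame,
                   ci: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Cronbach's alpha with the Feldt F-distribution confidence interval.

    ``alpha = k/(k-1) * (1 - sum(item variances) / variance(total score))``.
    """
    m = np.asarray(item_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("need >= 3 participants and >= 2 items")
    n, k = m.shape
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero-variance total score")
    item_var = m.var(axis=0, ddof=1).sum()
    alpha = k / (k - 1) * (1.0 - item_var / total_var)
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    q = (1 - ci) / 2
    lower = 1.0 - (1.0 - alpha) * stats.f.isf(q, df1, df2)
    upper = 1.0 - (1.0 - alpha) * stats.f.ppf(q, df1, df2)
    return float(alpha), (float(lower), float(upper))
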