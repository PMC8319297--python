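"""Small-area estimation via multilevel regression with synthetic
poststratification (MrsP) and spatial smoothing.

The response model is Gaussian on the continuous moral-value scores:

``y_i = mu + sum_v u_v[level_v(i)] + r[region(i)] + x_area' delta
        + theta_s[area(i)] + theta_u[area(i)] + e_i``

with partially pooled demographic effects ``u_v ~ N(0, sd_v^2)``, region
effects ``r ~ N(0, sd_r^2)``, and the area effect decomposed into an
intrinsic autoregressive (ICAR) component ``theta_s`` — scaled so its
marginal variance matches ``sd_s^2`` and constrained to sum to zero within
each connected component — plus an unstructured component
``theta_u ~ N(0, sd_u^2)``. Under spatial autocorrelation the ICAR prior
smooths estimates between adjacent areas. A derived ``spatial_mix``
parameter reports ``sd_s^2 / (sd_s^2 + sd_u^2)``.

All conditionals are conjugate Gaussian, so the model is fit by blocked
Gibbs sampling with slice-sampling updates for the scale hyperparameters
(half-normal priors). Poststratification weights the posterior cell
predictions by the population cell counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ebep.samplers import slice_sample
from ebep.types import AreaGraph, PosteriorDraws
from ebep.synthetic import icar_scale


@dataclass
class ResponseModelSpec:
    """Configuration of the individual-level response model."""

    demographics: tuple[str, ...]
    response: str = "binding_score"
    area_covariates: tuple[str, ...] = ()
    pooling: str = "partial"  # "partial" | "none" (flat prior on the full cell)
    include_region: bool = True
    include_spatial: bool = True
    include_area_iid: bool = True
    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    seed: int = 0
    prior_scales: dict = field(default_factory=lambda: {
        "sd": 1.0, "sigma": 2.0, "slope": 1.0, "intercept": 10.0})

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if self.pooling not in ("partial", "none"):
            raise ValueError("pooling must be 'partial' or 'none'")


CELL_FACTOR = "__cell__"
_FLAT_SD = 100.0  # effectively flat prior when pooling is disabled


def _halfnormal_scale_logp(log_sd: float, ss: float, n_terms: float,
                           prior_scale: float) -> float:
    sd = np.exp(log_sd)
    return (-n_terms * log_sd - ss / (2.0 * sd * sd)
            - sd * sd / (2.0 * prior_scale * prior_scale) + log_sd)


def fit_response_model(
    survey: pd.DataFrame,
    graph: AreaGraph,
    covariates: pd.DataFrame | None,
    spec: ResponseModelSpec,
) -> PosteriorDraws:
    """Fit the multilevel response model by blocked Gibbs sampling.

    ``covariates`` is an area-indexed frame providing the columns named in
    ``spec.area_covariates``; they are z-scored internally and the
    transform is stored with the fit so prediction reuses it.
    """
    for v in spec.demographics:
        if v not in survey.columns:
            raise ValueError(f"demographic variable {v!r} missing from survey")
    if spec.response not in survey.columns:
        raise ValueError(f"response column {spec.response!r} missing from survey")
    y = survey[spec.response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite responses")
    n = len(y)

    area_index = graph.index_of()
    unknown = set(survey["area_id"]) - set(area_index)
    if unknown:
        raise ValueError(f"survey areas not in graph: {sorted(unknown)[:5]}")
    area_codes = survey["area_id"].map(area_index).to_numpy()
    n_area = graph.n_areas
    region_codes_by_area = graph.region_codes()
    region_codes = region_codes_by_area[area_codes]
    n_region = len(graph.regions())

    # factor blocks: partially pooled demographics, or one flat cell factor
    factors: dict[str, tuple[np.ndarray, list]] = {}
    if spec.pooling == "partial":
        for v in spec.demographics:
            levels = sorted(survey[v].astype(str).unique())
            lut = {l: i for i, l in enumerate(levels)}
            factors[v] = (survey[v].astype(str).map(lut).to_numpy(), levels)
    else:
        key = survey[list(spec.demographics)].astype(str).agg("|".join, axis=1)
        levels = sorted(key.unique())
        lut = {l: i for i, l in enumerate(levels)}
        factors[CELL_FACTOR] = (key.map(lut).to_numpy(), levels)

    # standardized area covariates expanded to rows
    cov_names = list(spec.area_covariates)
    cov_mean: dict[str, float] = {}
    cov_sd: dict[str, float] = {}
    if cov_names:
        if covariates is None:
            raise ValueError("area covariates named in spec but none supplied")
        x_area = np.empty((n_area, len(cov_names)))
        for j, name in enumerate(cov_names):
            col = covariates[name].reindex(list(graph.area_ids)).to_numpy(dtype=float)
            if np.any(~np.isfinite(col)):
                raise ValueError(f"covariate {name!r} missing for some area")
            m, s = float(col.mean()), float(col.std(ddof=0))
            s = s if s > 0 else 1.0
            cov_mean[name], cov_sd[name] = m, s
            x_area[:, j] = (col - m) / s
        x_rows = x_area[area_codes]
    else:
        x_area = np.zeros((n_area, 0))
        x_rows = np.zeros((n, 0))

    qs = icar_scale(graph) if spec.include_spatial else None
    components = graph.components()
    icar_rank = sum(max(len(c) - 1, 0) for c in components)
    singletons = np.array([c[0] for c in components if len(c) == 1], dtype=int)

    n_by_area = np.bincount(area_codes, minlength=n_area).astype(float)
    n_by_region = np.bincount(region_codes, minlength=n_region).astype(float)

    ps = spec.prior_scales
    names_to_store = (["intercept", "sigma", "area_effect"]
                      + [f"u_{f}" for f in factors]
                      + [f"sd_{f}" for f in factors if spec.pooling == "partial"])
    store: dict[str, list] = {}

    def run_chain(chain_seed: int) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(chain_seed)
        mu = float(y.mean()) + rng.normal(0, 0.1)
        sigma = max(float(y.std(ddof=0)), 0.1) * np.exp(rng.normal(0, 0.1))
        u = {f: np.zeros(len(levels)) for f, (_, levels) in factors.items()}
        sd_f = {f: (0.5 if spec.pooling == "partial" else _FLAT_SD) for f in factors}
        r_eff = np.zeros(n_region)
        sd_r = 0.5
        delta = np.zeros(len(cov_names))
        th_s = np.zeros(n_area)
        th_u = np.zeros(n_area)
        sd_s, sd_u = 0.5, 0.5

        def eta() -> np.ndarray:
            e = np.full(n, mu)
            for f, (codes, _) in factors.items():
                e += u[f][codes]
            if spec.include_region:
                e += r_eff[region_codes]
            if cov_names:
                e += x_rows @ delta
            if spec.include_spatial:
                e += th_s[area_codes]
            if spec.include_area_iid:
                e += th_u[area_codes]
            return e

        cur = eta()
        total = spec.warmup + spec.draws
        out = {name: [] for name in _draw_names()}
        for it in range(total):
            s2 = sigma * sigma
            # intercept
            resid = y - (cur - mu)
            prec = n / s2 + 1.0 / ps["intercept"] ** 2
            m = resid.sum() / s2 / prec
            new_mu = m + rng.normal() / np.sqrt(prec)
            cur += new_mu - mu
            mu = new_mu
            # factor effects
            for f, (codes, levels) in factors.items():
                L = len(levels)
                resid = y - (cur - u[f][codes])
                sums = np.bincount(codes, weights=resid, minlength=L)
                ns = np.bincount(codes, minlength=L).astype(float)
                prec = ns / s2 + 1.0 / sd_f[f] ** 2
                mean = sums / s2 / prec
                new_u = mean + rng.normal(size=L) / np.sqrt(prec)
                cur += new_u[codes] - u[f][codes]
                u[f] = new_u
                if spec.pooling == "partial":
                    ss = float(new_u @ new_u)
                    log_sd = slice_sample(
                        lambda t, ss=ss, L=L: _halfnormal_scale_logp(t, ss, L, ps["sd"]),
                        np.log(sd_f[f]), rng)
                    sd_f[f] = float(np.exp(np.clip(log_sd, -10, 10)))
            # region effects
            if spec.include_region:
                resid = y - (cur - r_eff[region_codes])
                sums = np.bincount(region_codes, weights=resid, minlength=n_region)
                prec = n_by_region / s2 + 1.0 / sd_r ** 2
                mean = sums / s2 / prec
                new_r = mean + rng.normal(size=n_region) / np.sqrt(prec)
                cur += new_r[region_codes] - r_eff[region_codes]
                r_eff = new_r
                ss = float(new_r @ new_r)
                log_sd = slice_sample(
                    lambda t: _halfnormal_scale_logp(t, ss, n_region, ps["sd"]),
                    np.log(sd_r), rng)
                sd_r = float(np.exp(np.clip(log_sd, -10, 10)))
            # area covariate slopes
            if cov_names:
                resid = y - (cur - x_rows @ delta)
                a = x_rows.T @ x_rows / s2 + np.eye(len(cov_names)) / ps["slope"] ** 2
                b = x_rows.T @ resid / s2
                ch = np.linalg.cholesky(a)
                mean = np.linalg.solve(a, b)
                new_d = mean + np.linalg.solve(ch.T, rng.normal(size=len(cov_names)))
                cur += x_rows @ (new_d - delta)
                delta = new_d
            # spatial (ICAR) component
            if spec.include_spatial:
                resid = y - (cur - th_s[area_codes])
                b = np.bincount(area_codes, weights=resid, minlength=n_area) / s2
                prec_mat = qs / sd_s ** 2 + np.diag(n_by_area / s2)
                for comp in components:
                    if len(comp) >= 2:
                        # soft sum-to-zero: sum(theta_c) ~ N(0, (0.001*|c|)^2)
                        w = 1.0 / (0.001 * len(comp)) ** 2
                        prec_mat[np.ix_(comp, comp)] += w
                if len(singletons):
                    prec_mat[singletons, singletons] += 1e8
                ch = np.linalg.cholesky(prec_mat)
                mean = np.linalg.solve(prec_mat, b)
                new_s = mean + np.linalg.solve(ch.T, rng.normal(size=n_area))
                cur += new_s[area_codes] - th_s[area_codes]
                th_s = new_s
                ss = float(th_s @ qs @ th_s)
                log_sd = slice_sample(
                    lambda t: _halfnormal_scale_logp(t, ss, icar_rank, ps["sd"]),
                    np.log(sd_s), rng)
                sd_s = float(np.exp(np.clip(log_sd, -10, 10)))
            # unstructured area component
            if spec.include_area_iid:
                resid = y - (cur - th_u[area_codes])
                sums = np.bincount(area_codes, weights=resid, minlength=n_area)
                prec = n_by_area / s2 + 1.0 / sd_u ** 2
                mean = sums / s2 / prec
                new_t = mean + rng.normal(size=n_area) / np.sqrt(prec)
                cur += new_t[area_codes] - th_u[area_codes]
                th_u = new_t
                ss = float(th_u @ th_u)
                log_sd = slice_sample(
                    lambda t: _halfnormal_scale_logp(t, ss, n_area, ps["sd"]),
                    np.log(sd_u), rng)
                sd_u = float(np.exp(np.clip(log_sd, -10, 10)))
            # translation moves: the likelihood only identifies mu plus the
            # block means, so sample the exact conditional of a joint shift
            # (u -> u - m, mu -> mu + m) along each additive block to break
            # the random-walk coupling between the intercept and the blocks
            def _recenter(vec: np.ndarray, sd_vec: float) -> float:
                nonlocal mu
                L = len(vec)
                prec = L / sd_vec ** 2 + 1.0 / ps["intercept"] ** 2
                mean = (vec.sum() / sd_vec ** 2 - mu / ps["intercept"] ** 2) / prec
                m = mean + rng.normal() / np.sqrt(prec)
                vec -= m
                mu += m
                return m

            if spec.pooling == "partial":
                for f in factors:
                    _recenter(u[f], sd_f[f])
            if spec.include_region:
                _recenter(r_eff, sd_r)
            if spec.include_area_iid:
                _recenter(th_u, sd_u)
            # residual scale
            rss = float(((y - cur) ** 2).sum())
            log_sig = slice_sample(
                lambda t: _halfnormal_scale_logp(t, rss, n, ps["sigma"]),
                np.log(sigma), rng)
            sigma = float(np.exp(np.clip(log_sig, -10, 10)))

            if it >= spec.warmup:
                out["intercept"].append(mu)
                out["sigma"].append(sigma)
                for f in factors:
                    out[f"u_{f}"].append(u[f].copy())
                    if spec.pooling == "partial":
                        out[f"sd_{f}"].append(sd_f[f])
                if spec.include_region:
                    out["region_effect"].append(r_eff.copy())
                    out["sd_region"].append(sd_r)
                if cov_names:
                    out["delta"].append(delta.copy())
                if spec.include_spatial:
                    out["theta_spatial"].append(th_s.copy())
                    out["sd_spatial"].append(sd_s)
                if spec.include_area_iid:
                    out["theta_iid"].append(th_u.copy())
                    out["sd_iid"].append(sd_u)
                area_eff = np.zeros(n_area)
                if spec.include_spatial:
                    area_eff = area_eff + th_s
                if spec.include_area_iid:
                    area_eff = area_eff + th_u
                out["area_effect"].append(area_eff)
                if spec.include_spatial and spec.include_area_iid:
                    out["spatial_mix"].append(sd_s ** 2 / (sd_s ** 2 + sd_u ** 2))
        return {k: np.asarray(v) for k, v in out.items() if len(v)}

    def _draw_names() -> list[str]:
        names = ["intercept", "sigma", "area_effect"]
        for f in factors:
            names.append(f"u_{f}")
            if spec.pooling == "partial":
                names.append(f"sd_{f}")
        if spec.include_region:
            names += ["region_effect", "sd_region"]
        if cov_names:
            names.append("delta")
        if spec.include_spatial:
            names += ["theta_spatial", "sd_spatial"]
        if spec.include_area_iid:
            names += ["theta_iid", "sd_iid"]
        if spec.include_spatial and spec.include_area_iid:
            names.append("spatial_mix")
        return names

    seqs = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    chain_draws = [run_chain(int(s.generate_state(1)[0] % (2 ** 31))) for s in seqs]
    draws = {name: np.stack([cd[name] for cd in chain_draws])
             for name in chain_draws[0]}
    meta = {
        "model": "smallarea_gibbs",
        "factors": {f: levels for f, (_, levels) in factors.items()},
        "demographics": list(spec.demographics),
        "pooling": spec.pooling,
        "area_ids": list(graph.area_ids),
        "region_codes_by_area": region_codes_by_area.tolist(),
        "cov_names": cov_names,
        "cov_mean": cov_mean,
        "cov_sd": cov_sd,
        "include_region": spec.include_region,
        "include_spatial": spec.include_spatial,
        "include_area_iid": spec.include_area_iid,
        "response": spec.response,
    }
    fit = PosteriorDraws(draws, meta=meta)
    fit.diagnostics["sampler"] = "gibbs"
    return fit


# ---------------------------------------------------------------------------
# Synthetic joint via iterative proportional fitting
# ---------------------------------------------------------------------------

def synthesize_joint_ipf(
    area_margins: Mapping[str, Mapping[str, "pd.Series | Mapping[str, float]"]],
    external_joint: pd.Series,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Per-area joint cell tables matching supplied margins, seeded at an
    externally sourced joint distribution (adjusted-MrsP joint synthesis).

    ``external_joint`` is a probability Series over the full cell product
    (MultiIndex named by variable, strictly positive on its support);
    ``area_margins[area][var]`` maps levels to counts (or shares) with the
    same total across variables. Classic iterative proportional fitting:
    starting from the external joint, each sweep rescales along every
    variable to match that variable's margin; the fixed point preserves the
    external joint's interaction structure while honoring the margins.
    """
    joint = external_joint.sort_index()
    var_names = list(joint.index.names)
    shape = tuple(len(lv) for lv in joint.index.levels)
    base = joint.to_numpy(dtype=float).reshape(shape)
    if np.any(base < 0):
        raise ValueError("external joint must be nonnegative")
    frames = []
    cell_levels = joint.index.to_frame(index=False)
    for area, margins in area_margins.items():
        targets = []
        totals = []
        for vi, v in enumerate(var_names):
            if v not in margins:
                raise ValueError(f"area {area!r}: margin for {v!r} missing")
            m = pd.Series(margins[v]).reindex(joint.index.levels[vi])
            if m.isna().any():
                raise ValueError(f"area {area!r}: margin for {v!r} missing levels")
            t = m.to_numpy(dtype=float)
            targets.append(t)
            totals.append(t.sum())
        if not np.allclose(totals, totals[0], rtol=1e-6):
            raise ValueError(f"area {area!r}: margin totals disagree across variables")
        total = totals[0]
        table = base.copy() * total / base.sum()
        axes_other = [tuple(j for j in range(len(shape)) if j != i)
                      for i in range(len(shape))]
        converged = False
        for _ in range(max_iter):
            for i, tgt in enumerate(targets):
                cur = table.sum(axis=axes_other[i])
                if np.any((cur == 0) & (tgt > 0)):
                    raise ValueError(
                        f"area {area!r}: margin requires mass on a zero-support "
                        f"slice of variable {var_names[i]!r}")
                ratio = np.where(cur > 0, tgt / np.where(cur > 0, cur, 1.0), 1.0)
                table *= ratio.reshape([-1 if j == i else 1 for j in range(len(shape))])
            dev = max(
                float(np.abs(table.sum(axis=axes_other[i]) - targets[i]).max())
                for i in range(len(shape)))
            if dev <= tol * max(total, 1.0):
                converged = True
                break
        if not converged:
            raise RuntimeError(
                f"IPF failed to converge for area {area!r} within {max_iter} sweeps "
                f"(max margin deviation {dev:.3g})")
        df = cell_levels.copy()
        df.insert(0, "area_id", area)
        df["count"] = table.reshape(-1)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Prediction and poststratification
# ---------------------------------------------------------------------------

def predict_cells(
    draws: PosteriorDraws,
    cells: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    seed: int = 0,
    max_draws: int | None = None,
) -> np.ndarray:
    """Posterior linear-predictor value for every frame cell.

    Returns an array of shape ``(n_posterior_draws, n_cells)`` aligned with
    the rows of ``cells`` (no residual noise added). Demographic levels
    never seen in the survey draw their effect from the pooled prior
    ``N(0, sd_v)`` per posterior draw, so a synthetic frame may contain
    cells absent from a biased survey.
    """
    meta = draws.meta
    rng = np.random.default_rng(seed)
    mu = draws.stacked("intercept")
    S = len(mu)
    keep = slice(None)
    if max_draws is not None and S > max_draws:
        keep = np.linspace(0, S - 1, max_draws).astype(int)
        mu = mu[keep]
        S = len(mu)
    pred = np.tile(mu[:, None], (1, len(cells)))

    if meta["pooling"] == "none":
        key = cells[meta["demographics"]].astype(str).agg("|".join, axis=1)
        pred += _factor_contrib(draws, CELL_FACTOR, key, meta, rng, keep)
    else:
        for v in meta["demographics"]:
            pred += _factor_contrib(draws, v, cells[v].astype(str), meta, rng, keep)

    area_lut = {a: i for i, a in enumerate(meta["area_ids"])}
    unknown = set(cells["area_id"]) - set(area_lut)
    if unknown:
        raise ValueError(f"cells reference areas not in the fit: {sorted(unknown)[:5]}")
    area_codes = cells["area_id"].map(area_lut).to_numpy()
    pred += draws.stacked("area_effect")[keep][:, area_codes]
    if meta["include_region"]:
        reg = np.asarray(meta["region_codes_by_area"])[area_codes]
        pred += draws.stacked("region_effect")[keep][:, reg]
    if meta["cov_names"]:
        if covariates is None:
            raise ValueError("fit used area covariates; supply them for prediction")
        delta = draws.stacked("delta")[keep]
        for j, name in enumerate(meta["cov_names"]):
            col = covariates[name].reindex(cells["area_id"]).to_numpy(dtype=float)
            if np.any(~np.isfinite(col)):
                raise ValueError(f"covariate {name!r} missing for some area")
            z = (col - meta["cov_mean"][name]) / meta["cov_sd"][name]
            pred += delta[:, j][:, None] * z[None, :]
    return pred


def _factor_contrib(draws: PosteriorDraws, factor: str, values: pd.Series,
                    meta: dict, rng, keep) -> np.ndarray:
    levels = meta["factors"][factor]
    lut = {l: i for i, l in enumerate(levels)}
    u = draws.stacked(f"u_{factor}")[keep]
    S = u.shape[0]
    unseen = sorted(set(values) - set(lut))
    if unseen:
        if meta["pooling"] == "none":
            raise ValueError(f"unseen cells with pooling disabled: {unseen[:5]}")
        sd = draws.stacked(f"sd_{factor}")[keep]
        extra = rng.normal(size=(S, len(unseen))) * sd[:, None]
        u = np.concatenate([u, extra], axis=1)
        for j, l in enumerate(unseen):
            lut[l] = len(levels) + j
    codes = values.map(lut).to_numpy()
    return u[:, codes]


def poststratify(
    cell_preds: np.ndarray,
    cells: pd.DataFrame,
    return_draws: bool = False,
):
    """Population-weighted area estimates from cell-level predictions.

    Per posterior draw, the area value is the cell-count-weighted mean of
    the cell predictions; the result is summarized to posterior mean, SD
    and central 95% interval per area.
    """
    cell_preds = np.asarray(cell_preds)
    if cell_preds.shape[1] != len(cells):
        raise ValueError("cell_preds and cells are misaligned")
    counts = cells["count"].to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative cell counts")
    area_ids = cells["area_id"].to_numpy()
    uniq, inv = np.unique(area_ids, return_inverse=True)
    totals = np.bincount(inv, weights=counts)
    if np.any(totals <= 0):
        bad = uniq[totals <= 0]
        raise ValueError(f"areas with zero total population: {bad[:5].tolist()}")
    # weighted sums per area, vectorized over draws
    num = np.zeros((cell_preds.shape[0], len(uniq)))
    for a in range(len(uniq)):
        mask = inv == a
        num[:, a] = cell_preds[:, mask] @ counts[mask]
    area_draws = num / totals[None, :]
    lo, hi = np.percentile(area_draws, [2.5, 97.5], axis=0)
    est = pd.DataFrame({
        "area_id": uniq,
        "mean": area_draws.mean(axis=0),
        "sd": area_draws.std(axis=0, ddof=1),
        "q2.5": lo,
        "q97.5": hi,
    })
    if return_draws:
        return est, area_draws
    return est


# ---------------------------------------------------------------------------
# Gold-standard validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Association between area estimates and a gold-standard vector."""

    r: float
    df: int
    t: float
    p: float
    rmse: float
    n: int

    def to_dict(self) -> dict:
        return {"r": self.r, "df": self.df, "t": self.t, "p": self.p,
                "rmse": self.rmse, "n": self.n}


def validate_against_gold(estimates: pd.DataFrame | pd.Series,
                          gold: Mapping[str, float] | pd.Series) -> ValidationReport:
    """Pearson correlation (with t statistic on n-2 df) and RMSE between
    poststratified estimates and a gold-standard area measure."""
    if isinstance(estimates, pd.DataFrame):
        est = pd.Series(estimates["mean"].to_numpy(), index=estimates["area_id"])
    else:
        est = pd.Series(estimates)
    gold = pd.Series(gold)
    common = est.index.intersection(gold.index)
    if len(common) < 3:
        raise ValueError("need at least 3 overlapping areas")
    x = est.loc[common].to_numpy(dtype=float)
    g = gold.loc[common].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(g) == 0:
        raise ValueError("correlation undefined for constant inputs")
    n = len(common)
    r = float(stats.pearsonr(x, g).statistic)
    df = n - 2
    denom = max(1.0 - r * r, 1e-15)
    t = r * np.sqrt(df) / np.sqrt(denom)
    p = float(2 * stats.t.sf(abs(t), df))
    rmse = float(np.sqrt(np.mean((x - g) ** 2)))
    return ValidationReport(r=r, df=df, t=float(t), p=p, rmse=rmse, n=n)
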