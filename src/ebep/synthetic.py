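"""Synthetic-data generators for every pipeline input, with recorded truth.

The generators emulate the data sources the pipeline was designed around,
none of which are shareable or reproducible at desk scale:

* a lattice geography standing in for the US county map, with contiguous
  region bands standing in for states;
* per-area joint demographic population tables over six variables —
  gender (2), age (3), ethnicity (4), education (3), religious attendance
  (3), political ideology (3) — 648 cells per area;
* a spatially autocorrelated latent surface of area-level moral values;
* a large opt-in survey with demographic selection bias (the opt-in panel
  skews strongly liberal, so unweighted area means are biased);
* area counts of hate groups with a population exposure (per 10,000
  inhabitants);
* vignette experiments with a continuous mediator (perceived moral
  wrongness, PMW) and four 7-point EBEP-justification items per participant.

Every generator returns its data together with a :class:`~ebep.types.TruthRecord`
(or a truth payload merged into one) so that downstream estimators can be
tested for parameter recovery. All generators are deterministic given
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ebep.types import AreaGraph, TruthRecord

#: Demographic variables and their levels (frame defaults; configurable).
DEMOGRAPHIC_LEVELS: dict[str, tuple[str, ...]] = {
    "gender": ("female", "male"),
    "age": ("18-34", "35-54", "55+"),
    "ethnicity": ("white", "black", "hispanic", "other"),
    "education": ("hs_or_less", "some_college", "college"),
    "attendance": ("never", "sometimes", "weekly"),
    "ideology": ("liberal", "moderate", "conservative"),
}

#: EBEP justification items, ordered by severity of norm violation.
EBEP_ITEMS = ("facebook", "flyer", "verbal", "physical")

_DEFAULT_MARGINS = {
    "gender": (0.51, 0.49),
    "age": (0.30, 0.35, 0.35),
    "ethnicity": (0.60, 0.13, 0.18, 0.09),
    "education": (0.40, 0.30, 0.30),
    "attendance": (0.45, 0.30, 0.25),
    "ideology": (0.33, 0.34, 0.33),
}


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------

def make_lattice_geography(n_rows: int, n_cols: int, n_regions: int,
                           seed: int = 0) -> AreaGraph:
    """Rook-adjacency rectangular lattice partitioned into contiguous regions.

    Areas are labelled ``a<row>_<col>``; regions are contiguous bands of
    roughly equal size in row-major order (``seed`` is accepted for API
    uniformity; the partition is deterministic).
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be positive")
    n = n_rows * n_cols
    if not (1 <= n_regions <= n):
        raise ValueError("n_regions must be in [1, n_rows*n_cols]")
    ids = [f"a{r}_{c}" for r in range(n_rows) for c in range(n_cols)]
    edges = []
    for r in range(n_rows):
        for c in range(n_cols):
            if c + 1 < n_cols:
                edges.append((ids[r * n_cols + c], ids[r * n_cols + c + 1]))
            if r + 1 < n_rows:
                edges.append((ids[r * n_cols + c], ids[(r + 1) * n_cols + c]))
    bounds = np.linspace(0, n, n_regions + 1).round().astype(int)
    region_of = {}
    for g in range(n_regions):
        for i in range(bounds[g], bounds[g + 1]):
            region_of[ids[i]] = f"r{g}"
    return AreaGraph(tuple(ids), tuple(edges), region_of)


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

def default_national_joint(seed: int = 0, perturb_sd: float = 0.15,
                           levels: Mapping[str, Sequence[str]] | None = None,
                           margins: Mapping[str, Sequence[float]] | None = None,
                           ) -> pd.Series:
    """National joint demographic distribution: product of margins times a
    seeded log-linear perturbation (the real external joint is unavailable).

    Returns a probability Series over the full Cartesian product of levels,
    indexed by a MultiIndex named after the variables.
    """
    levels = dict(levels or DEMOGRAPHIC_LEVELS)
    margins = dict(margins or {k: _DEFAULT_MARGINS[k] for k in levels if k in _DEFAULT_MARGINS})
    idx = pd.MultiIndex.from_product([levels[v] for v in levels], names=list(levels))
    logp = np.zeros(len(idx))
    for vi, v in enumerate(levels):
        m = np.asarray(margins.get(v, np.ones(len(levels[v])) / len(levels[v])), dtype=float)
        m = m / m.sum()
        codes = idx.codes[vi]
        logp += np.log(m)[codes]
    rng = np.random.default_rng(seed)
    if perturb_sd > 0:
        logp += rng.normal(0.0, perturb_sd, size=len(idx))
    p = np.exp(logp - logp.max())
    return pd.Series(p / p.sum(), index=idx, name="prob")


def _largest_remainder(p: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` with shares as close to p as possible."""
    raw = p * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base))
        base[order[:short]] += 1
    return base


def make_population_cells(
    graph: AreaGraph,
    national_joint: pd.Series,
    concentration: float,
    populations: Mapping[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-area joint demographic counts (the poststratification frame).

    Each area's joint is a Dirichlet(concentration * national_joint) draw,
    converted to integer counts summing exactly to the area population by
    largest-remainder rounding. ``concentration=inf`` gives every area the
    national joint.
    """
    p = np.asarray(national_joint, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("national_joint must sum to 1")
    if np.any(p < 0):
        raise ValueError("national_joint must be nonnegative")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    frames = []
    cell_levels = national_joint.index.to_frame(index=False)
    for area in graph.area_ids:
        pop = int(populations[area])
        if pop <= 0:
            raise ValueError(f"population for {area!r} must be positive")
        if np.isinf(concentration):
            pa = p
        else:
            alpha = np.maximum(concentration * p, 1e-12)
            pa = rng.dirichlet(alpha)
        counts = _largest_remainder(pa, pop)
        df = cell_levels.copy()
        df.insert(0, "area_id", area)
        df["count"] = counts
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Latent spatial surface
# ---------------------------------------------------------------------------

def icar_scale(graph: AreaGraph) -> np.ndarray:
    """Per-component scaling of the graph Laplacian so an intrinsic
    autoregressive field has (geometric-mean) unit marginal variance.

    Returns the scaled Laplacian Q*; singleton components get zero rows.
    """
    q = graph.laplacian()
    qs = np.zeros_like(q)
    for comp in graph.components():
        if len(comp) < 2:
            continue
        sub = q[np.ix_(comp, comp)]
        # generalized inverse restricted to the sum-to-zero subspace
        w, v = np.linalg.eigh(sub)
        pos = w > 1e-10 * w.max()
        diag_pinv = (v[:, pos] ** 2 / w[pos]).sum(axis=1)
        gm = float(np.exp(np.mean(np.log(diag_pinv))))
        qs[np.ix_(comp, comp)] = sub * gm
    return qs


def _icar_draw(graph: AreaGraph, rng: np.random.Generator) -> np.ndarray:
    """One draw from the scaled intrinsic autoregressive prior
    (sum-to-zero per connected component; zero on singletons)."""
    qs = icar_scale(graph)
    phi = np.zeros(graph.n_areas)
    for comp in graph.components():
        if len(comp) < 2:
            continue
        sub = qs[np.ix_(comp, comp)]
        w, v = np.linalg.eigh(sub)
        pos = w > 1e-10 * w.max()
        z = rng.normal(size=pos.sum())
        phi[comp] = v[:, pos] @ (z / np.sqrt(w[pos]))
    return phi


def draw_latent_surface(
    graph: AreaGraph,
    spatial_sd: float = 1.0,
    iid_sd: float = 1.0,
    rho_mix: float = 0.7,
    seed: int = 0,
) -> tuple[pd.Series, TruthRecord]:
    """Latent area surface: convex mix of a scaled ICAR field and iid noise.

    ``latent = rho_mix * spatial + (1 - rho_mix) * iid`` with the spatial
    part scaled to ``spatial_sd`` and the iid part to ``iid_sd``. The
    spatial term sums to zero within each connected component.
    """
    if spatial_sd < 0 or iid_sd < 0:
        raise ValueError("standard deviations must be nonnegative")
    if not (0.0 <= rho_mix <= 1.0):
        raise ValueError("rho_mix must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    spatial = spatial_sd * _icar_draw(graph, rng)
    iid = iid_sd * rng.normal(size=graph.n_areas)
    latent = rho_mix * spatial + (1.0 - rho_mix) * iid
    ids = list(graph.area_ids)
    truth = TruthRecord(
        seed=seed,
        latent_spatial=dict(zip(ids, (rho_mix * spatial).tolist())),
        latent_iid=dict(zip(ids, ((1 - rho_mix) * iid).tolist())),
        latent_total=dict(zip(ids, latent.tolist())),
        extras={"spatial_sd": spatial_sd, "iid_sd": iid_sd, "rho_mix": rho_mix},
    )
    return pd.Series(latent, index=ids, name="latent"), truth


# ---------------------------------------------------------------------------
# Biased opt-in survey
# ---------------------------------------------------------------------------

def default_selection_weights(cells: pd.DataFrame,
                              ideology_bias: Mapping[str, float] | None = None,
                              education_bias: Mapping[str, float] | None = None,
                              ) -> np.ndarray:
    """Opt-in selection weights emulating a self-selected morality survey:
    liberal and college-educated respondents are heavily overrepresented."""
    ideology_bias = ideology_bias or {"liberal": 6.0, "moderate": 1.5, "conservative": 1.0}
    education_bias = education_bias or {"hs_or_less": 0.5, "some_college": 1.0, "college": 2.0}
    w = np.ones(len(cells))
    if "ideology" in cells:
        w = w * cells["ideology"].map(ideology_bias).to_numpy(dtype=float)
    if "education" in cells:
        w = w * cells["education"].map(education_bias).to_numpy(dtype=float)
    return w


def sample_biased_survey(
    cells: pd.DataFrame,
    latent: pd.Series | Mapping[str, float],
    demographic_effects: Mapping[str, Mapping[str, float]] | None,
    selection_weights: np.ndarray | None,
    n: int,
    noise_sd: float = 1.0,
    seed: int = 0,
    intercept: float = 0.0,
    outcome_col: str = "binding_score",
    replace: bool = True,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw a non-representative survey from the population frame.

    Respondents are sampled with probability proportional to
    ``cell count x selection weight`` (uniform weights give a representative
    sample). The outcome for a respondent in cell c of area a is
    ``intercept + sum_v effect_v[level_v(c)] + latent_a + N(0, noise_sd)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    demo_vars = [c for c in cells.columns if c not in ("area_id", "count")]
    counts = cells["count"].to_numpy(dtype=float)
    w = np.ones(len(cells)) if selection_weights is None else np.asarray(selection_weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("selection weights must be positive")
    probs = counts * w
    total_pop = counts.sum()
    if not replace and n > total_pop:
        raise ValueError("n exceeds population for sampling without replacement")
    rng = np.random.default_rng(seed)
    if replace:
        idx = rng.choice(len(cells), size=n, p=probs / probs.sum())
    else:
        # expand to persons (cells carry integer counts)
        person_cell = np.repeat(np.arange(len(cells)), counts.astype(int))
        pw = np.repeat(w / counts.clip(min=1), counts.astype(int))
        chosen = rng.choice(len(person_cell), size=n, replace=False, p=pw / pw.sum())
        idx = person_cell[chosen]
    sampled = cells.iloc[idx].reset_index(drop=True)
    latent_map = pd.Series(latent)
    out = pd.DataFrame({"respondent_id": np.arange(n), "area_id": sampled["area_id"].to_numpy()})
    for v in demo_vars:
        out[v] = sampled[v].to_numpy()
    y = np.full(n, float(intercept))
    effects = {v: dict(m) for v, m in (demographic_effects or {}).items()}
    for v, mapping in effects.items():
        y += out[v].map(mapping).fillna(0.0).to_numpy(dtype=float)
    y += out["area_id"].map(latent_map).to_numpy(dtype=float)
    y += rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
    out[outcome_col] = y
    truth = TruthRecord(
        seed=seed,
        demographic_effects=effects,
        latent_total={str(k): float(vv) for k, vv in latent_map.items()},
        extras={"intercept": intercept, "noise_sd": noise_sd, "outcome_col": outcome_col},
    )
    return out, truth


# ---------------------------------------------------------------------------
# Area counts (hate groups per 10,000 inhabitants)
# ---------------------------------------------------------------------------

def draw_area_counts(
    graph: AreaGraph,
    covariates: pd.DataFrame,
    coefficients: Mapping[str, float],
    latent: pd.Series | Mapping[str, float] | None,
    dispersion: float,
    exposures: pd.Series | Mapping[str, float],
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Negative-binomial area counts with a log link and exposure offset.

    ``count_a ~ NB(mean = exposure_a * exp(intercept + x_a' beta + latent_a),
    dispersion)``. Exposures are populations divided by 10,000 (rate per
    10,000 inhabitants). ``coefficients`` maps covariate names to effects
    and may include ``"intercept"``.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    exposures = pd.Series(exposures)
    exp_arr = exposures.reindex(list(graph.area_ids)).to_numpy(dtype=float)
    if np.any(~np.isfinite(exp_arr)) or np.any(exp_arr <= 0):
        raise ValueError("exposures must be positive for every area")
    eta = np.full(graph.n_areas, float(coefficients.get("intercept", 0.0)))
    for name, b in coefficients.items():
        if name == "intercept":
            continue
        eta += float(b) * covariates[name].reindex(list(graph.area_ids)).to_numpy(dtype=float)
    if latent is not None:
        eta += pd.Series(latent).reindex(list(graph.area_ids)).to_numpy(dtype=float)
    if np.any(~np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    mu = exp_arr * np.exp(eta)
    rng = np.random.default_rng(seed)
    if np.isinf(dispersion):
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=dispersion, scale=mu / dispersion)
        counts = rng.poisson(lam)
    table = pd.DataFrame({"area_id": list(graph.area_ids), "count": counts,
                          "exposure": exp_arr})
    truth = TruthRecord(
        seed=seed,
        count_coefficients={str(k): float(v) for k, v in coefficients.items()},
        extras={"dispersion": dispersion},
    )
    return table, truth


# ---------------------------------------------------------------------------
# Vignette experiments with built-in mediation structure
# ---------------------------------------------------------------------------

@dataclass
class MediationPaths:
    """Ground-truth path coefficients for the experiment generator.

    The mediator (PMW) and the latent justification scale follow

    ``pmw = pmw_intercept + a[arm] + a_binding*binding_z
            + a_individualizing*individualizing_z
            + a_treat_x_binding*treat*binding_z + N(0, pmw_noise_sd)``

    ``y* = cprime[arm] + b*pmw_z + b_binding*binding_z
           + b_individualizing*individualizing_z + b_pmw_x_binding*pmw_z*binding_z
           + participant intercept + item intercept + item slope * treat``

    where ``treat`` is the indicator of a violation arm and ``pmw_z`` is the
    sample-standardized mediator (the same standardization the analysis
    models use). Defaults reproduce the reference shape of the 3-arm study:
    control-arm PMW mean ~2.15 versus ~5.55 / ~5.48 in the violation arms,
    with right-skewed justification responses (modal category 1).
    """

    pmw_intercept: float = 2.15
    a: Mapping[str, float] = field(default_factory=lambda: {
        "control": 0.0, "binding": 3.40, "individualizing": 3.33, "violation": 3.40})
    a_binding: float = 0.3
    a_individualizing: float = 0.0
    a_treat_x_binding: float = 0.0
    pmw_noise_sd: float = 1.7
    b: float = 1.2
    b_binding: float = 0.4
    b_individualizing: float = -0.2
    b_pmw_x_binding: float = 0.0
    cprime: Mapping[str, float] = field(default_factory=lambda: {
        "control": 0.0, "binding": 0.3, "individualizing": 0.3, "violation": 0.3})


DEFAULT_CUTPOINTS = (1.2, 2.4, 3.3, 4.1, 5.0, 6.0)


def make_experiment_data(
    n: int,
    design: str = "3-arm",
    paths: MediationPaths | None = None,
    cutpoints: Sequence[float] = DEFAULT_CUTPOINTS,
    re_sds: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Randomized vignette experiment with mediator and 4 ordinal items.

    ``design`` is ``"2-arm"`` (control vs. violation) or ``"3-arm"``
    (control vs. binding vs. individualizing violation). Each participant
    contributes 4 rows (one per EBEP item); responses are 7-point ordinal,
    generated by cumulative-logit thresholding of the latent justification
    scale at ``cutpoints`` (6 strictly increasing reals).
    """
    if design not in ("2-arm", "3-arm"):
        raise ValueError("design must be '2-arm' or '3-arm'")
    arms = ("control", "violation") if design == "2-arm" else (
        "control", "binding", "individualizing")
    if n < 2 * len(arms):
        raise ValueError("need at least 2 participants per arm")
    cut = np.asarray(cutpoints, dtype=float)
    if cut.size != 6 or np.any(np.diff(cut) <= 0):
        raise ValueError("cutpoints must be 6 strictly increasing reals")
    paths = paths or MediationPaths()
    re_sds = dict(re_sds or {})
    sd_p = float(re_sds.get("participant", 1.0))
    sd_item_int = float(re_sds.get("item_intercept", 0.8))
    sd_item_slope = float(re_sds.get("item_slope", 0.3))

    rng = np.random.default_rng(seed)
    cond = np.tile(arms, n // len(arms) + 1)[:n]
    binding = rng.normal(size=n)
    individualizing = rng.normal(size=n)
    religiosity = rng.normal(size=n)
    ideology = np.clip(np.rint(rng.normal(3.0, 1.8, size=n)), 1, 7).astype(int)
    treat = (cond != "control").astype(float)

    a_arm = np.array([paths.a.get(c, 0.0) for c in cond])
    pmw = (paths.pmw_intercept + a_arm + paths.a_binding * binding
           + paths.a_individualizing * individualizing
           + paths.a_treat_x_binding * treat * binding)
    if paths.pmw_noise_sd > 0:
        pmw = pmw + rng.normal(0.0, paths.pmw_noise_sd, size=n)
    pmw_z = (pmw - pmw.mean()) / pmw.std(ddof=0)

    item_int = rng.normal(0.0, sd_item_int, size=4) if sd_item_int > 0 else np.zeros(4)
    item_slope = rng.normal(0.0, sd_item_slope, size=4) if sd_item_slope > 0 else np.zeros(4)
    u_p = rng.normal(0.0, sd_p, size=n) if sd_p > 0 else np.zeros(n)
    c_arm = np.array([paths.cprime.get(c, 0.0) for c in cond])
    eta_person = (c_arm + paths.b * pmw_z + paths.b_binding * binding
                  + paths.b_individualizing * individualizing
                  + paths.b_pmw_x_binding * pmw_z * binding + u_p)

    rows = []
    for j, item in enumerate(EBEP_ITEMS):
        eta = eta_person + item_int[j] + item_slope[j] * treat
        # cumulative logit: P(Y <= k) = expit(c_k - eta)
        u = rng.uniform(size=n)
        from scipy.special import expit
        cdf = expit(cut[None, :] - eta[:, None])  # (n, 6)
        resp = 1 + (u[:, None] > cdf).sum(axis=1)
        rows.append(pd.DataFrame({
            "participant_id": np.arange(n),
            "condition": cond,
            "treat": treat,
            "binding_z": binding,
            "individualizing_z": individualizing,
            "religiosity_z": religiosity,
            "ideology": ideology,
            "pmw": pmw,
            "pmw_z": pmw_z,
            "item_id": item,
            "response": resp.astype(int),
        }))
    data = pd.concat(rows, ignore_index=True).sort_values(
        ["participant_id", "item_id"], kind="stable").reset_index(drop=True)
    truth = TruthRecord(
        seed=seed,
        mediation_paths={
            "pmw_intercept": paths.pmw_intercept,
            **{f"a[{k}]": float(v) for k, v in paths.a.items() if k in arms},
            "a_binding": paths.a_binding,
            "a_individualizing": paths.a_individualizing,
            "a_treat_x_binding": paths.a_treat_x_binding,
            "pmw_noise_sd": paths.pmw_noise_sd,
            "b": paths.b,
            "b_binding": paths.b_binding,
            "b_individualizing": paths.b_individualizing,
            "b_pmw_x_binding": paths.b_pmw_x_binding,
            **{f"cprime[{k}]": float(v) for k, v in paths.cprime.items() if k in arms},
        },
        extras={
            "design": design,
            "cutpoints": list(map(float, cut)),
            "re_sds": {"participant": sd_p, "item_intercept": sd_item_int,
                       "item_slope": sd_item_slope},
        },
    )
    return data, truth
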