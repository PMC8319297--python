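import numpy as np
import pandas as pd
import pytest

from ebep import synthetic
from ebep.types import PosteriorDraws


@pytest.fixture(scope="session")
def grid_3x3():
    return synthetic.make_lattice_geography(3, 3, 2, seed=0)


@pytest.fixture(scope="session")
def grid_5x5():
    return synthetic.make_lattice_geography(5, 5, 3, seed=0)


@pytest.fixture(scope="session")
def national_joint():
    return synthetic.default_national_joint(seed=0)


def make_ordinal_draws(
    cutpoints,
    betas: dict,
    item_effect,
    item_slopes: dict | None = None,
    sd_participant: float = 0.0,
    n_draws: int = 40,
    chains: int = 2,
    rng: np.random.Generator | None = None,
    jitter: float = 0.0,
) -> PosteriorDraws:
    """Fabricate cumulative-logit posterior draws with known values, for
    deterministic checks of the probability and mediation machinery."""
    item_effect = np.asarray(item_effect, dtype=float)
    n_items = len(item_effect)
    rng = rng or np.random.default_rng(0)

    def rep(value, extra_shape=()):
        arr = np.broadcast_to(np.asarray(value, dtype=float),
                              (chains, n_draws) + extra_shape).copy()
        if jitter:
            arr += rng.normal(0, jitter, size=arr.shape)
        return arr

    draws = {
        "cutpoints": rep(np.asarray(cutpoints, dtype=float), (len(cutpoints),)),
        "item_effect": rep(item_effect, (n_items,)),
        "sd_participant": rep(sd_participant),
        "sd_item": rep(np.std(item_effect) or 0.1),
        "z_participant": rep(np.zeros(2), (2,)),
    }
    for term, val in betas.items():
        draws[f"b_{term}"] = rep(val)
    item_slopes = item_slopes or {}
    for term, vals in item_slopes.items():
        draws[f"item_slope_{term}"] = rep(np.asarray(vals, dtype=float), (n_items,))
        draws[f"sd_item_slope_{term}"] = rep(np.std(vals) or 0.1)
    meta = {
        "model": "cumulative_logit",
        "fixed_terms": list(betas),
        "item_slope_terms": list(item_slopes),
        "items": [f"item{j}" for j in range(n_items)],
        "n_participants": 2,
        "response": "response",
    }
    return PosteriorDraws(draws, diagnostics={"fabricated": True}, meta=meta)


def make_smallarea_draws(
    area_ids,
    intercept: float,
    factor_effects: dict,
    area_effect=None,
    region_codes=None,
    region_effect=None,
    n_draws: int = 20,
    chains: int = 2,
) -> PosteriorDraws:
    """Fabricate MrsP response-model draws with known effect values."""
    n_area = len(area_ids)

    def rep(value, extra_shape=()):
        return np.broadcast_to(np.asarray(value, dtype=float),
                               (chains, n_draws) + extra_shape).copy()

    draws = {
        "intercept": rep(intercept),
        "sigma": rep(1.0),
        "area_effect": rep(area_effect if area_effect is not None
                           else np.zeros(n_area), (n_area,)),
    }
    factors = {}
    for name, level_map in factor_effects.items():
        levels = sorted(level_map)
        factors[name] = levels
        draws[f"u_{name}"] = rep([level_map[l] for l in levels], (len(levels),))
        draws[f"sd_{name}"] = rep(1.0)
    include_region = region_effect is not None
    if include_region:
        draws["region_effect"] = rep(region_effect, (len(region_effect),))
        draws["sd_region"] = rep(1.0)
    meta = {
        "model": "smallarea_gibbs",
        "factors": factors,
        "demographics": list(factor_effects),
        "pooling": "partial",
        "area_ids": list(area_ids),
        "region_codes_by_area": (list(region_codes) if region_codes is not None
                                 else [0] * n_area),
        "cov_names": [],
        "cov_mean": {},
        "cov_sd": {},
        "include_region": include_region,
        "include_spatial": True,
        "include_area_iid": True,
        "response": "y",
    }
    return PosteriorDraws(draws, diagnostics={"fabricated": True}, meta=meta)


def brute_force_moran(values: np.ndarray, adjacency: np.ndarray) -> float:
    """Moran's I straight from the definition, kept independent of the
    package implementation."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    z = x - x.mean()
    num = 0.0
    w_sum = 0.0
    for i in range(n):
        for j in range(n):
            if adjacency[i, j]:
                num += z[i] * z[j]
                w_sum += adjacency[i, j]
    return n / w_sum * num / (z @ z)
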