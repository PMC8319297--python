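"""Shared containers: area graphs, posterior draws, and ground-truth records."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AreaGraph:
    """Undirected contiguity graph over small areas, nested in regions.

    Areas play the role of counties and regions the role of states: two
    levels of geographic clustering. Edges are unordered pairs of area ids
    (rook adjacency on a lattice in the synthetic geography). The graph may
    be disconnected; islands are allowed.
    """

    area_ids: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    region_of: Mapping[str, str]

    def __post_init__(self) -> None:
        ids = set(self.area_ids)
        if len(ids) != len(self.area_ids):
            raise ValueError("duplicate area ids")
        seen = set()
        canon = []
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on area {a!r}")
            if a not in ids or b not in ids:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown area")
            key = (a, b) if a <= b else (b, a)
            if key not in seen:
                seen.add(key)
                canon.append(key)
        object.__setattr__(self, "edges", tuple(sorted(canon)))
        missing = ids - set(self.region_of)
        if missing:
            raise ValueError(f"areas without a region: {sorted(missing)[:5]}")

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def index_of(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.area_ids)}

    def edge_indices(self) -> np.ndarray:
        """Edges as an (m, 2) integer array in area order."""
        idx = self.index_of()
        if not self.edges:
            return np.empty((0, 2), dtype=int)
        return np.array([(idx[a], idx[b]) for a, b in self.edges], dtype=int)

    def adjacency_matrix(self) -> np.ndarray:
        a = np.zeros((self.n_areas, self.n_areas))
        e = self.edge_indices()
        if len(e):
            a[e[:, 0], e[:, 1]] = 1.0
            a[e[:, 1], e[:, 0]] = 1.0
        return a

    def laplacian(self) -> np.ndarray:
        a = self.adjacency_matrix()
        return np.diag(a.sum(axis=1)) - a

    def components(self) -> list[np.ndarray]:
        """Connected components as arrays of area indices."""
        from scipy.sparse.csgraph import connected_components
        from scipy.sparse import csr_matrix

        n, labels = connected_components(csr_matrix(self.adjacency_matrix()))
        return [np.flatnonzero(labels == c) for c in range(n)]

    def regions(self) -> list[str]:
        return sorted(set(self.region_of.values()))

    def region_codes(self) -> np.ndarray:
        """Integer region code per area (in region-sorted order)."""
        regs = {r: i for i, r in enumerate(self.regions())}
        return np.array([regs[self.region_of[a]] for a in self.area_ids])


def summarize_draws(x: np.ndarray) -> dict[str, float]:
    """Posterior mean, sd, and central 95% interval of a flattened draw array."""
    flat = np.asarray(x).reshape(-1)
    lo, hi = np.percentile(flat, [2.5, 97.5])
    return {
        "mean": float(flat.mean()),
        "sd": float(flat.std(ddof=1)),
        "q2.5": float(lo),
        "q97.5": float(hi),
    }


class PosteriorDraws:
    """Named posterior draws with sampler diagnostics.

    ``draws[name]`` has shape ``(chain, draw)`` for scalars or
    ``(chain, draw, k)`` for vector parameters. This is the common currency
    between the fitting stages and the summarize/poststratify/mediate
    stages. ``meta`` carries model-specific plumbing (design information,
    standardization constants) needed to make predictions from the draws.
    """

    def __init__(
        self,
        draws: Mapping[str, np.ndarray],
        diagnostics: dict[str, Any] | None = None,
        meta: dict[str, Any] | None = None,
    ) -> None:
        self.draws = {k: np.asarray(v) for k, v in draws.items()}
        for name, arr in self.draws.items():
            if arr.ndim < 2:
                raise ValueError(f"draws for {name!r} must be (chain, draw, ...)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite draws for {name!r}")
        self.meta = dict(meta or {})
        self.diagnostics = diagnostics if diagnostics is not None else self.compute_diagnostics()

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def __contains__(self, name: str) -> bool:
        return name in self.draws

    def stacked(self, name: str) -> np.ndarray:
        """Draws for ``name`` with chains stacked: shape (chain*draw, ...)."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def compute_diagnostics(self) -> dict[str, Any]:
        import arviz as az

        idata = az.convert_to_dataset({k: v for k, v in self.draws.items()})
        rhat = az.rhat(idata)
        ess = az.ess(idata)
        out: dict[str, Any] = {"rhat": {}, "ess_bulk": {}, "divergences": 0}
        for name in self.draws:
            out["rhat"][name] = float(np.nanmax(np.atleast_1d(rhat[name].values)))
            out["ess_bulk"][name] = float(np.nanmin(np.atleast_1d(ess[name].values)))
        out["max_rhat"] = max(out["rhat"].values()) if out["rhat"] else float("nan")
        return out

    def summary(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        names = list(names) if names is not None else list(self.draws)
        rows = []
        for name in names:
            arr = self.stacked(name)
            if arr.ndim == 1:
                rows.append({"parameter": name, **summarize_draws(arr)})
            else:
                for j in range(arr.shape[1]):
                    rows.append({"parameter": f"{name}[{j}]", **summarize_draws(arr[:, j])})
        return pd.DataFrame(rows)

    def to_long_frame(self) -> pd.DataFrame:
        """Columnar (chain, draw, parameter, value) frame for CSV export."""
        recs = []
        for name, arr in self.draws.items():
            c, d = arr.shape[:2]
            flat = arr.reshape(c, d, -1)
            for j in range(flat.shape[2]):
                label = name if flat.shape[2] == 1 and arr.ndim == 2 else f"{name}[{j}]"
                df = pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), d),
                        "draw": np.tile(np.arange(d), c),
                        "parameter": label,
                        "value": flat[:, :, j].reshape(-1),
                    }
                )
                recs.append(df)
        return pd.concat(recs, ignore_index=True)


@dataclass
class TruthRecord:
    """Ground truth emitted by every synthetic-data generator run.

    Recovery tests compare posterior estimates against these values. All
    generated data are reproducible from (config, seed).
    """

    seed: int | None = None
    latent_spatial: dict[str, float] = field(default_factory=dict)
    latent_iid: dict[str, float] = field(default_factory=dict)
    latent_total: dict[str, float] = field(default_factory=dict)
    demographic_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    count_coefficients: dict[str, float] = field(default_factory=dict)
    mediation_paths: dict[str, float] = field(default_factory=dict)
    extras: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_json_default)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(**payload)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
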