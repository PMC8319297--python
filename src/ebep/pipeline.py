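"""Study-shaped end-to-end scenarios: simulate -> fit -> summarize -> mediate.

Presets mirror the two-track structure of the original investigation on
synthetic data with known ground truth:

* ``study1`` — geospatial track: biased survey over a lattice geography,
  MrsP small-area estimation with spatial smoothing, validation against the
  latent truth, then a spatially filtered negative-binomial regression of
  area counts on the estimated values (plus the ML fixed-effects contrast).
* ``study2`` / ``study3`` — observational experiments: ordinal justification
  items regressed on moral values and PMW; mediation of a 1-SD increase in
  binding values through PMW.
* ``study4`` — adds a randomized 2-arm manipulation.
* ``study5`` — 3-arm design with moderated mediation (ACME at binding
  values pinned to +/- 1 SD).

Every run is fully determined by (config, seed); the report lists every
emitted file with a content hash and every stage's seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from ebep import io, mediation, ordinal, smallarea, spatial_count, synthetic
from ebep.types import TruthRecord

SCENARIOS = ("study1", "study2", "study3", "study4", "study5", "custom")


@dataclass
class ScenarioConfig:
    scenario: str = "study5"
    seed: int = 0
    out_dir: str = "ebep_run"
    n_participants: int = 450
    survey_n: int = 2000
    grid: tuple[int, int] = (8, 8)
    n_regions: int = 4
    chains: int = 2
    draws: int = 400
    warmup: int = 400
    mediation_sims: int = 100
    threshold: int = 2
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        if "grid" in payload:
            payload["grid"] = tuple(payload["grid"])
        return cls(**payload)


@dataclass
class RunReport:
    scenario: str
    seed: int
    stages: dict[str, Any] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)
    started: float = field(default_factory=time.time)

    def record_file(self, path) -> None:
        self.files[str(path)] = io.file_sha256(path)

    def to_dict(self) -> dict:
        return asdict(self)


def check_or_summary(log_coefficient: float) -> float:
    """Exponentiate a log-scale coefficient to the ratio scale, rounded to
    the 2-decimal report precision (e.g. 1.60 -> 4.95, 1.63 -> 5.10)."""
    if not np.isfinite(log_coefficient):
        raise ValueError("log coefficient must be finite")
    return float(np.round(np.exp(log_coefficient), 2))


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _study1(cfg: ScenarioConfig, out: Path, report: RunReport) -> None:
    rng_seed = cfg.seed
    graph = synthetic.make_lattice_geography(*cfg.grid, cfg.n_regions, seed=rng_seed)
    joint = synthetic.default_national_joint(seed=rng_seed)
    pops = {a: 20_000 for a in graph.area_ids}
    cells = synthetic.make_population_cells(graph, joint, concentration=300.0,
                                            populations=pops, seed=rng_seed + 1)
    latent, truth_latent = synthetic.draw_latent_surface(
        graph, spatial_sd=0.5, iid_sd=0.2, rho_mix=0.8, seed=rng_seed + 2)
    effects = {"ideology": {"liberal": -0.6, "moderate": 0.0, "conservative": 0.6},
               "attendance": {"never": -0.2, "sometimes": 0.0, "weekly": 0.3}}
    survey, truth_survey = synthetic.sample_biased_survey(
        cells, latent, effects, synthetic.default_selection_weights(cells),
        n=cfg.survey_n, noise_sd=1.0, seed=rng_seed + 3, intercept=3.5)
    io.write_adjacency(graph, out / "adjacency.txt")
    io.write_regions(graph, out / "regions.csv")
    cells.to_csv(out / "cells.csv", index=False)
    survey.to_csv(out / "survey.csv", index=False)

    spec = smallarea.ResponseModelSpec(
        demographics=tuple(synthetic.DEMOGRAPHIC_LEVELS),
        response="binding_score", chains=cfg.chains, draws=cfg.draws,
        warmup=cfg.warmup, seed=rng_seed + 4)
    fit = smallarea.fit_response_model(survey, graph, None, spec)
    preds = smallarea.predict_cells(fit, cells, seed=rng_seed + 5, max_draws=400)
    est = smallarea.poststratify(preds, cells)
    est.to_csv(out / "estimates.csv", index=False)
    truth_area = pd.Series(truth_latent.latent_total) + 3.5
    val = smallarea.validate_against_gold(est, truth_area)
    io.write_json(val.to_dict(), out / "validation.json")
    report.stages["smallarea"] = {
        "seed": rng_seed + 4, "validation": val.to_dict(),
        "max_rhat": fit.diagnostics["max_rhat"],
    }

    # count track: binding estimate as the covariate of interest
    cov = pd.DataFrame({"binding_est": est.set_index("area_id")["mean"]})
    cov["binding_est"] = (cov["binding_est"] - cov["binding_est"].mean())
    true_ratio = float(cfg.overrides.get("count_ratio", 1.3))
    exposures = pd.Series({a: pops[a] / 10_000 for a in graph.area_ids})
    counts, truth_counts = synthetic.draw_area_counts(
        graph, cov / (cov.std(ddof=0) + 1e-12),
        {"intercept": -0.7, "binding_est": np.log(true_ratio)},
        None, dispersion=2.0, exposures=exposures, seed=rng_seed + 6)
    counts.to_csv(out / "counts.csv", index=False)
    k = spatial_count.default_basis_size(graph)
    basis = spatial_count.moran_eigenvector_basis(graph, k)
    nb_spec = spatial_count.NBSpec(chains=cfg.chains, draws=cfg.draws,
                                   warmup=cfg.warmup, seed=rng_seed + 7)
    nb_fit = spatial_count.fit_nb_spatial_filter(counts, cov, basis, nb_spec)
    ratios = spatial_count.summarize_rate_ratios(nb_fit)
    ratios.to_csv(out / "coefficients.csv", index=False)
    io.write_draws_csv(nb_fit, out / "nb_draws.csv")
    fe = spatial_count.fit_nb_fixed_effects(
        counts, cov, {a: graph.region_of[a] for a in graph.area_ids},
        include_fe=True)
    no_fe = spatial_count.fit_nb_fixed_effects(counts, cov, None, include_fe=False)
    report.stages["spatial_count"] = {
        "seed": rng_seed + 7,
        "true_ratio": true_ratio,
        "ratios": ratios.to_dict(orient="records"),
        "fe_coef": float(fe.loc[fe["term"] == "binding_est", "coef"].iloc[0]),
        "no_fe_coef": float(no_fe.loc[no_fe["term"] == "binding_est", "coef"].iloc[0]),
        "divergences": nb_fit.diagnostics["divergences"],
    }
    truth = TruthRecord(seed=cfg.seed,
                        latent_total=truth_latent.latent_total,
                        demographic_effects=truth_survey.demographic_effects,
                        count_coefficients=truth_counts.count_coefficients)
    io.write_truth(truth, out / "truth.json")


_PRESET_TERMS = {
    "study2": {
        "mediator": ("binding_z", "individualizing_z", "ideology"),
        "outcome": ("binding_z", "individualizing_z", "ideology", "pmw_z"),
        "slopes": ("pmw_z",),
        "treatment": ("binding_z", (0.0, 1.0)),
    },
    "study3": {
        "mediator": ("binding_z", "individualizing_z", "ideology"),
        "outcome": ("binding_z", "individualizing_z", "ideology", "pmw_z"),
        "slopes": ("pmw_z",),
        "treatment": ("binding_z", (0.0, 1.0)),
    },
    "study4": {
        "mediator": ("treat", "binding_z", "individualizing_z"),
        "outcome": ("treat", "binding_z", "individualizing_z", "pmw_z"),
        "slopes": ("treat", "pmw_z"),
        "treatment": ("treat", (0.0, 1.0)),
    },
    "study5": {
        "mediator": ("treat", "binding_z", "individualizing_z",
                     "treat:binding_z", "treat:individualizing_z",
                     "religiosity_z", "ideology"),
        "outcome": ("treat", "binding_z", "individualizing_z",
                    "treat:binding_z", "treat:individualizing_z",
                    "religiosity_z", "ideology", "pmw_z",
                    "pmw_z:binding_z", "pmw_z:individualizing_z"),
        "slopes": ("treat", "pmw_z"),
        "treatment": ("treat", (0.0, 1.0)),
    },
}


def _experiment_paths(scenario: str) -> synthetic.MediationPaths:
    if scenario in ("study2", "study3"):
        # observational: no manipulation, mediation flows from binding values
        return synthetic.MediationPaths(
            a={"control": 0.0, "violation": 0.0}, a_binding=0.8,
            cprime={"control": 0.0, "violation": 0.0}, b=1.0, b_binding=0.5)
    if scenario == "study4":
        return synthetic.MediationPaths(
            a={"control": 0.0, "violation": 3.4}, cprime={"control": 0.0,
                                                          "violation": 0.3})
    return synthetic.MediationPaths(
        a_treat_x_binding=0.6, b_pmw_x_binding=0.5)


def _experiment_scenario(cfg: ScenarioConfig, out: Path, report: RunReport) -> None:
    preset = _PRESET_TERMS[cfg.scenario]
    design = "3-arm" if cfg.scenario == "study5" else "2-arm"
    paths = _experiment_paths(cfg.scenario)
    data, truth = synthetic.make_experiment_data(
        cfg.n_participants, design=design, paths=paths, seed=cfg.seed)
    data.to_csv(out / "experiment.csv", index=False)
    io.write_truth(truth, out / "truth.json")

    if cfg.scenario == "study5":
        keep = data["condition"].isin(["control", "binding"])
        analysis = data[keep].reset_index(drop=True)
    else:
        analysis = data
    participants = analysis.drop_duplicates("participant_id").reset_index(drop=True)

    med_fit = mediation.fit_mediator(
        participants, preset["mediator"], response="pmw_z",
        chains=cfg.chains, draws=cfg.draws, seed=cfg.seed + 1)
    spec = ordinal.OrdinalModelSpec(
        fixed_terms=preset["outcome"], item_slope_terms=preset["slopes"],
        chains=cfg.chains, draws=cfg.draws, warmup=cfg.warmup,
        seed=cfg.seed + 2)
    out_fit = ordinal.fit_cumulative_model(analysis, spec)
    io.write_draws_csv(out_fit, out / "ordinal_draws.csv")
    coef_names = [f"b_{t}" for t in preset["outcome"]]
    out_fit.summary(coef_names).to_csv(out / "coefficients.csv", index=False)
    report.stages["ordinal"] = {
        "seed": cfg.seed + 2,
        "max_rhat": out_fit.diagnostics["max_rhat"],
        "divergences": out_fit.diagnostics["divergences"],
        "or_binding": check_or_summary(
            float(out_fit.stacked("b_binding_z").mean())),
    }

    treat_col, treat_vals = preset["treatment"]
    if cfg.scenario == "study5":
        grids = {}
        for mod in ("binding_z", "individualizing_z"):
            grids[mod] = mediation.moderated_mediation_grid(
                med_fit, out_fit, analysis, moderator=mod,
                threshold=cfg.threshold, n_sims=cfg.mediation_sims,
                seed=cfg.seed + 3, treatment_col=treat_col,
                treat_values=treat_vals)
        io.write_json({m: g.to_dict() for m, g in grids.items()},
                      out / "mediation.json")
        report.stages["mediation"] = {
            "seed": cfg.seed + 3,
            **{m: g.to_dict() for m, g in grids.items()},
        }
    else:
        eff = mediation.estimate_mediation_effects(
            med_fit, out_fit, analysis, threshold=cfg.threshold,
            n_sims=cfg.mediation_sims, seed=cfg.seed + 3,
            treatment_col=treat_col, treat_values=treat_vals)
        io.write_json(eff.to_dict(), out / "mediation.json")
        report.stages["mediation"] = {"seed": cfg.seed + 3, **eff.to_dict()}


def run_scenario(config: ScenarioConfig) -> RunReport:
    """Run a preset end-to-end and write all outputs plus a report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(scenario=config.scenario, seed=config.seed)
    stage = "setup"
    try:
        if config.scenario == "study1":
            stage = "study1"
            _study1(config, out, report)
        elif config.scenario in ("study2", "study3", "study4", "study5"):
            stage = config.scenario
            _experiment_scenario(config, out, report)
        else:
            raise ValueError("custom scenarios are driven via the library API")
    except Exception as err:  # persist the partial manifest, then re-raise
        for f in sorted(out.glob("*")):
            if f.is_file():
                report.record_file(f)
        io.write_json({"failed_stage": stage, "error": str(err),
                       **report.to_dict()}, out / "report.json")
        raise RuntimeError(f"scenario stage {stage!r} failed: {err}") from err
    write_tables(report, out)
    return report


def write_tables(report: RunReport, out_dir) -> None:
    """Write the run report (JSON) and log; records content hashes for every
    emitted file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for f in sorted(out.glob("*")):
        if f.is_file() and f.name not in ("report.json", "run.log"):
            report.record_file(f)
    io.write_json(report.to_dict(), out / "report.json")
    lines = [f"scenario={report.scenario} seed={report.seed}"]
    for name, payload in report.stages.items():
        lines.append(f"[{name}] {payload}")
    for path, digest in report.files.items():
        lines.append(f"{digest[:12]}  {path}")
    (out / "run.log").write_text("\n".join(lines) + "\n", encoding="utf-8")
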