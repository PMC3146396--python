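"""End-to-end scenario orchestration: synthesize, quantify, simulate, fit.

:func:`run_full` drives the whole analysis from a single
:class:`ScenarioConfig`: generate the synthetic world, quantify the
synthetic network's own error budget by semivariogram analysis, run the
configured Monte Carlo error scenarios against the health model, compute
observed and predicted attenuation (plus an optional error-type continuum
sweep), and write tabular outputs with a provenance manifest.  All
randomness is funnelled through seeds spawned deterministically from one
master seed, so reruns are bit-for-bit reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attenuation import (
    ScenarioResult,
    compare_predicted_observed,
    continuum_sweep,
    run_scenario,
)
from .epi_model import build_confounder_design, fit_quasipoisson
from .error_model import ErrorSpec
from .exceptions import AnalysisError, ConfigurationError
from .reference import GAMMA_BAR
from .semivariance import (
    ErrorBudget,
    error_budget_table,
    fit_semivariogram,
    pairwise_log_correlations,
    population_weighted_semivariance,
)
from .series import MonitorField, PollutantSeries
from .synthetic import (
    HealthConfig,
    TractTable,
    WorldConfig,
    generate_confounders,
    generate_health_counts,
    generate_monitor_field,
    generate_tracts,
)

logger = logging.getLogger(__name__)

__all__ = ["ScenarioConfig", "run_full", "write_tracts_csv", "read_tracts_csv"]


def _child_seed(ss: np.random.SeedSequence) -> int:
    """A positive 31-bit integer seed spawned from a SeedSequence."""
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    """Full configuration for one end-to-end run.

    ``errors`` is a list of mappings, each with a ``label``, either a
    ``gamma_bar`` or a ``sigma_err``, and a ``types`` list drawn from
    {"B", "C"} (or explicit ``s_ratio`` values for intermediate types).
    """

    world: WorldConfig = dataclasses.field(default_factory=WorldConfig)
    health: HealthConfig = dataclasses.field(default_factory=HealthConfig)
    errors: tuple[Mapping[str, Any], ...] = ()
    n_sims: int = 1000
    n_tracts: int = 100
    use_confounders: bool = True
    min_overlap: int = 365
    sweep: Mapping[str, Any] | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.errors:
            object.__setattr__(
                self,
                "errors",
                tuple(
                    {"label": name, "gamma_bar": g, "types": ["B", "C"]}
                    for name, g in GAMMA_BAR.items()
                ),
            )
        labels = [e["label"] for e in self.errors]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("scenario labels must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        world = WorldConfig(**raw.get("world", {}))
        health_raw = dict(raw.get("health", {}))
        health = HealthConfig(**health_raw)
        return cls(
            world=world,
            health=health,
            errors=tuple(raw.get("errors", ())),
            n_sims=int(raw.get("n_sims", 1000)),
            n_tracts=int(raw.get("n_tracts", 100)),
            use_confounders=bool(raw.get("use_confounders", True)),
            min_overlap=int(raw.get("min_overlap", 365)),
            sweep=raw.get("sweep"),
            master_seed=int(raw.get("seed", raw.get("master_seed", 0))),
        )


def write_tracts_csv(tracts: TractTable, path: str | Path) -> None:
    tracts.table.to_csv(path, index=False)


def read_tracts_csv(path: str | Path, within_tract_distance: float = 1.0) -> TractTable:
    return TractTable(pd.read_csv(path), within_tract_distance=within_tract_distance)


def _spec_from_entry(
    entry: Mapping[str, Any], type_label: str, s_ratio: float | None,
    n_sims: int, seed: int,
) -> tuple[ErrorSpec, float | None]:
    kw = dict(type_label=type_label, s_ratio=s_ratio, n_sims=n_sims, seed=seed)
    if "gamma_bar" in entry:
        g = float(entry["gamma_bar"])
        return ErrorSpec.from_gamma_bar(g, **kw), g
    if "sigma_err" in entry:
        return ErrorSpec(sigma_err=float(entry["sigma_err"]), **kw), None
    raise ConfigurationError(f"error entry needs gamma_bar or sigma_err: {entry}")


def run_full(
    config: ScenarioConfig,
    outdir: str | Path,
    make_plots: bool = False,
) -> dict[str, Any]:
    """Run every stage and write CSV outputs plus a manifest to ``outdir``.

    Returns a bundle with the in-memory objects (field, tracts, budgets,
    scenario results, sweep table) for programmatic use.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("berksim")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_full_inner(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_full_inner(config: ScenarioConfig, outdir: Path) -> dict[str, Any]:
    master = np.random.SeedSequence(config.master_seed)
    seeds = {
        name: _child_seed(child)
        for name, child in zip(
            ("world", "tracts", "confounders", "health", "scenarios"), master.spawn(5)
        )
    }
    logger.info("stage synth: master seed %d -> %s", config.master_seed, seeds)

    world = dataclasses.replace(config.world, seed=seeds["world"])
    try:
        field = generate_monitor_field(world)
    except Exception as exc:
        raise AnalysisError(f"stage synth failed: {exc}") from exc
    field.to_frame().to_csv(outdir / "monitors.csv", index=False)
    field.coords.rename_axis("site_id").to_csv(outdir / "sites.csv")

    tracts = generate_tracts(
        config.n_tracts, extent_km=world.extent_km, seed=seeds["tracts"]
    )
    write_tracts_csv(tracts, outdir / "tracts.csv")

    confounders = (
        generate_confounders(world.n_days, seed=seeds["confounders"], start=world.start)
        if config.use_confounders
        else None
    )
    base = field.series[field.site_ids[0]]
    if not base.is_complete:
        base = base.dropna()
    health = dataclasses.replace(config.health, seed=seeds["health"])
    counts = generate_health_counts(base, confounders, health)
    counts_out = pd.DataFrame({"date": counts.index, "count": counts.to_numpy()})
    if confounders is not None:
        counts_out = counts_out.merge(
            confounders.reset_index(names="date"), on="date", how="left"
        )
    counts_out.to_csv(outdir / "counts.csv", index=False)

    # stage semivar: the synthetic network's own measured error budget
    logger.info("stage semivar")
    budgets: dict[str, ErrorBudget] = {}
    if field.n_sites >= 2:
        try:
            pairs = pairwise_log_correlations(field, min_overlap=config.min_overlap)
            svfit = fit_semivariogram(pairs, nugget=world.nugget)
            budgets["synthetic field"] = population_weighted_semivariance(svfit, tracts)
        except AnalysisError as exc:
            logger.warning("semivariance stage skipped: %s", exc)
    for entry in config.errors:
        if "gamma_bar" in entry:
            budgets[str(entry["label"])] = ErrorBudget.from_gamma_bar(
                float(entry["gamma_bar"])
            )
    budget_df = error_budget_table(budgets)
    budget_df.to_csv(outdir / "error_budget.csv", index=False)

    # stage simulate + epifit + attenuate
    logger.info("stage scenarios: %d error entries, n_sims=%d", len(config.errors), config.n_sims)
    design = build_confounder_design(confounders)
    fit_true = fit_quasipoisson(counts, base, design=design)
    results: list[ScenarioResult] = []
    for entry in config.errors:
        types = entry.get("types", ["B", "C"])
        for t in types:
            if isinstance(t, (int, float)):
                type_label, s_ratio = "intermediate", float(t)
            else:
                type_label, s_ratio = str(t), None
            spec, gamma = _spec_from_entry(
                entry, type_label, s_ratio, config.n_sims, seeds["scenarios"]
            )
            label = f"{entry['label']} [{type_label}]"
            logger.info("scenario %s: sigma_err=%.4f s=%.4f", label, spec.sigma_err, spec.s_ratio)
            results.append(
                run_scenario(
                    base, counts, spec, design=design, fit_true=fit_true,
                    label=label, gamma_bar=gamma,
                )
            )
    epi_rows = pd.DataFrame([r.to_row() for r in results])
    epi_cols = [
        "scenario", "type", "gamma_bar", "rr_unit", "rr_unit_lo", "rr_unit_hi",
        "iqr", "rr_iqr", "rr_iqr_lo", "rr_iqr_hi", "p",
    ]
    epi_rows[epi_cols].to_csv(outdir / "epi_results.csv", index=False)
    att_cols = [
        "scenario", "type", "gamma_bar", "sigma_err", "s_ratio",
        "att_unit_mean", "att_unit_sd", "att_iqr_mean", "att_iqr_sd",
        "att_unit_from_mean_rr", "att_iqr_from_mean_rr",
        "pred_unit_mean", "pred_iqr_mean", "m_mean", "raw_error_corr_mean",
    ]
    epi_rows[att_cols].to_csv(outdir / "attenuation.csv", index=False)

    comparison, concordance = (None, None)
    if len(results) >= 2:
        comparison, concordance = compare_predicted_observed(results)
        comparison.to_csv(outdir / "predicted_observed.csv", index=False)

    sweep_df = None
    if config.sweep is not None:
        sw = dict(config.sweep)
        if "gamma_bar" in sw:
            spec0 = ErrorSpec.from_gamma_bar(float(sw["gamma_bar"]), type_label="C")
            sigma = spec0.sigma_err
        else:
            sigma = float(sw["sigma_err"])
        logger.info("stage sweep: sigma_err=%.4f", sigma)
        sweep_df, _ = continuum_sweep(
            base,
            counts,
            sigma,
            n_steps=int(sw.get("n_steps", 9)),
            n_sims=int(sw.get("n_sims", config.n_sims)),
            seed=seeds["scenarios"],
            confounders=confounders,
        )
        sweep_df.to_csv(outdir / "sweep.csv", index=False)

    manifest = {
        "package": "berksim",
        "version": __version__,
        "master_seed": config.master_seed,
        "derived_seeds": seeds,
        "n_sims": config.n_sims,
        "world": dataclasses.asdict(world) if world.site_coords is None else {
            **dataclasses.asdict(world), "site_coords": [list(p) for p in world.site_coords]
        },
        "health": {
            "alpha": health.alpha,
            "beta_true": health.beta_true,
            "confounder_effects": dict(health.confounder_effects),
            "dispersion": health.dispersion,
        },
        "errors": [
            {**{k: v for k, v in e.items()}} for e in config.errors
        ],
        "scenarios": [
            {
                "label": r.label,
                "type": r.spec.type_label,
                "gamma_bar": r.gamma_bar,
                "sigma_err": round(r.spec.sigma_err, 6),
                "s_ratio": round(r.spec.s_ratio, 6),
            }
            for r in results
        ],
        "concordance": concordance,
        "base_case": {
            "rr_unit": fit_true.rr_unit,
            "rr_unit_ci": list(fit_true.rr_unit_ci),
            "iqr": fit_true.iqr_used,
            "p": fit_true.p,
        },
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(manifest, default=float)), fh, sort_keys=False)

    return {
        "field": field,
        "tracts": tracts,
        "base": base,
        "counts": counts,
        "fit_true": fit_true,
        "budgets": budgets,
        "budget_table": budget_df,
        "results": results,
        "epi_table": epi_rows,
        "comparison": comparison,
        "concordance": concordance,
        "sweep": sweep_df,
        "manifest": manifest,
    }
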