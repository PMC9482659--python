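"""End-to-end orchestration: generate -> prep -> model -> ensemble/project ->
metrics -> profiles, under a single config and seed.

Every stage is a pure function of the config and the previous stages'
outputs; the top-level seed fans out through stable per-species/per-replicate
sub-seeds (hash of the seed with the species id and replicate index), so two
runs with the same config are bit-identical and adding a species never
perturbs another. Species for which no ensemble member clears the evaluation
gate are logged as unmodelable and excluded from all downstream metrics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biodiversity_metrics import (
    PAM,
    HotspotResult,
    RangeChangeRecord,
    RichnessMaps,
    build_pam,
    delta_richness,
    hotspots,
    range_change,
    richness,
    temporal_sorensen,
)
from .climate_profiles import (
    GAIN_LOSS_VARIABLES,
    SCENARIO_DELTA_VARIABLES,
    ClimateProfile,
    gain_loss_profiles,
    scenario_delta_profile,
)
from .data_prep import (
    SpeciesRecordSet,
    cap_records,
    dedupe_and_filter,
    endemicity_check,
    mark_not_endemic,
    select_predictors,
)
from .ensemble_projection import (
    EnsembleMember,
    EnsemblePrediction,
    UnmodelableSpeciesError,
    algorithm_consensus_maps,
    build_ensemble,
    cv_across_algorithms,
    project,
)
from .grids import GridSpec, write_ascii_grid
from .niche_models import (
    ALGORITHMS,
    CalibrationRegion,
    build_m,
    build_projected_m,
    draw_pseudo_absences,
    evaluate,
    fit_algorithm,
    split_replicates,
    variable_contributions,
)
from .synthetic_world import (
    BASELINE,
    ClimateStack,
    NicheConfig,
    OccurrenceSet,
    VirtualSpecies,
    WorldMask,
    generate_climate,
    generate_scenarios,
    generate_virtual_species,
    generate_world,
    sample_occurrences,
    subseed,
    write_climate_stack,
    write_occurrences,
    write_species_truth,
    write_world_mask,
)

logger = logging.getLogger("endemia")

STAGES = ("generate", "prep", "model", "ensemble", "metrics", "profiles")

# Final-horizon drifts in baseline-sd units. The melting family exceeds the
# control family overall and especially on max temperature of the warmest
# month (bio05) and precipitation of the driest month (bio14), the variables
# a freshwater-forced scenario perturbs hardest relative to plain warming.
DEFAULT_CONTROL_SHIFT = {"bio01": 1.5, "bio05": 1.2, "bio12": -1.0, "bio14": -0.8}
DEFAULT_MELTING_SHIFT = {
    "bio01": 2.5,
    "bio05": 2.4,
    "bio12": -1.8,
    "bio14": -1.6,
    "bio04": 1.0,
    "bio15": 0.8,
}


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults are the study conditions."""

    seed: int = 0
    # world
    n_rows: int = 60
    n_cols: int = 60
    # 0.5-degree cells give a 30x30-degree world: countries span several
    # degrees, so the 4-degree accessible-area buffer and 2-degree projection
    # buffer keep their intended meaning at desk scale (the resolution is a
    # grid abstraction; buffers stay in the degree units the method states).
    cell_size: float = 0.5
    origin: tuple[float, float] = (0.0, 0.0)
    n_countries: int = 12
    ecoregions_per_country: int = 3
    autocorr_length: float = 4.0
    cross_corr: float = 0.85
    n_species: int = 30
    species_per_country: dict[int, int] | None = None
    occurrences_per_species: int = 300
    detection_noise: float = 0.0
    niche: NicheConfig = field(default_factory=NicheConfig)
    control_shift: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CONTROL_SHIFT))
    melting_shift: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MELTING_SHIFT))
    n_horizons: int = 3
    # data prep / modelling thresholds
    min_records: int = 25
    max_records: int = 500
    r_threshold: float = 0.8
    pa_n: int = 10000
    train_fraction: float = 0.7
    n_reps: int = 10
    auc_min: float = 0.7
    psh_factor: float = 0.6
    psh_factors: tuple[float, ...] = (0.2, 0.6, 0.9)
    endemic_buffer: float = 0.08333
    m_buffer: float = 4.0
    proj_buffer: float = 2.0
    algorithms: tuple[str, ...] = ALGORITHMS
    scenario_delta_variables: tuple[str, ...] = SCENARIO_DELTA_VARIABLES
    gain_loss_variables: tuple[str, ...] = GAIN_LOSS_VARIABLES
    out_dir: str | None = None

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.cell_size, tuple(self.origin))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "niche" in kwargs and isinstance(kwargs["niche"], dict):
            niche = kwargs["niche"]
            for key in ("n_vars", "sigma_range", "tau_range"):
                if key in niche:
                    niche[key] = tuple(niche[key])
            kwargs["niche"] = NicheConfig(**niche)
        if "species_per_country" in kwargs and kwargs["species_per_country"] is not None:
            kwargs["species_per_country"] = {
                int(k): int(v) for k, v in kwargs["species_per_country"].items()
            }
        for key in ("origin", "psh_factors", "algorithms",
                    "scenario_delta_variables", "gain_loss_variables"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["niche"] = dataclasses.asdict(self.niche)
        return d


def smoke_config(seed: int = 0, out_dir: str | None = None) -> RunConfig:
    """The tiny end-to-end configuration: 20x20 grid, 2 countries, 6 species."""
    return RunConfig(
        seed=seed,
        n_rows=20,
        n_cols=20,
        n_countries=2,
        ecoregions_per_country=2,
        n_species=6,
        occurrences_per_species=120,
        autocorr_length=2.0,
        min_records=10,  # a 20x20 world cannot hold 25-cell ranges reliably
        pa_n=2000,
        n_reps=4,
        out_dir=out_dir,
    )


@dataclass
class SpeciesModelRow:
    species_id: str
    algorithm: str
    replicate: int
    auc: float
    tss: float
    tss_threshold: float
    top_var1: str
    top_var2: str
    fallback_used: bool


@dataclass
class RunResult:
    """All in-memory artifacts of a pipeline run."""

    config: RunConfig
    baseline: ClimateStack | None = None
    scenarios: list[ClimateStack] = field(default_factory=list)
    mask: WorldMask | None = None
    species: list[VirtualSpecies] = field(default_factory=list)
    occurrences: list[OccurrenceSet] = field(default_factory=list)
    record_sets: dict[str, SpeciesRecordSet] = field(default_factory=dict)
    regions: dict[str, CalibrationRegion] = field(default_factory=dict)
    kept_layers: dict[str, list[str]] = field(default_factory=dict)
    members: dict[str, list[EnsembleMember]] = field(default_factory=dict)
    model_report: pd.DataFrame | None = None
    predictions: dict[tuple[str, str], dict[str, EnsemblePrediction]] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    cv_by_species: dict[str, float] = field(default_factory=dict)
    range_records: list[RangeChangeRecord] = field(default_factory=list)
    pams: dict[tuple[str, str], PAM] = field(default_factory=dict)
    richness_maps: dict[tuple[str, str], RichnessMaps] = field(default_factory=dict)
    hotspot_results: dict[tuple[float, str, str], HotspotResult] = field(default_factory=dict)
    bsor_maps: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    profiles: list[ClimateProfile] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    @property
    def modeled_species(self) -> list[str]:
        key = (BASELINE, "T0")
        return sorted(self.predictions.get(key, {}))

    def species_by_id(self, species_id: str) -> VirtualSpecies:
        return next(sp for sp in self.species if sp.species_id == species_id)

    def range_change_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(r) for r in self.range_records],
            columns=[
                "species_id", "scenario", "horizon", "n_present", "n_future",
                "delta", "complete_loss", "category",
            ],
        )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_generate(result: RunResult) -> None:
    cfg = result.config
    grid = cfg.grid
    result.baseline = generate_climate(grid, cfg.autocorr_length, cfg.cross_corr, cfg.seed)
    result.scenarios = generate_scenarios(
        result.baseline, cfg.control_shift, cfg.melting_shift, cfg.n_horizons, cfg.seed
    )
    result.mask = generate_world(grid, cfg.n_countries, cfg.ecoregions_per_country, cfg.seed)
    result.species = generate_virtual_species(
        result.baseline, result.mask, cfg.n_species, cfg.niche, cfg.seed,
        species_per_country=cfg.species_per_country,
    )
    result.occurrences = [
        sample_occurrences(sp, result.mask, cfg.occurrences_per_species,
                           cfg.detection_noise, cfg.seed)
        for sp in result.species
    ]
    logger.info("generated %d species on %dx%d grid", len(result.species), grid.n_rows, grid.n_cols)


def _stage_prep(result: RunResult) -> None:
    cfg = result.config
    grid = cfg.grid
    for occ in result.occurrences:
        s = dedupe_and_filter(occ, grid, cfg.min_records)
        if s.retained:
            s = cap_records(s, cfg.max_records, cfg.seed)
            if not endemicity_check(s, result.mask, cfg.endemic_buffer):
                s = mark_not_endemic(s)
        result.record_sets[s.species_id] = s
        if not s.retained:
            result.skipped[s.species_id] = s.exclusion_reason.value
            logger.info("excluded %s: %s", s.species_id, s.exclusion_reason.value)
    for sp_id, s in result.record_sets.items():
        if not s.retained:
            continue
        cr = build_m(s, result.mask, cfg.m_buffer)
        cr = build_projected_m(cr, result.mask, cfg.proj_buffer)
        result.regions[sp_id] = cr
        sel = select_predictors(result.baseline, cr.m_cells, cfg.r_threshold)
        result.kept_layers[sp_id] = sel.kept_layers


def _stage_model(result: RunResult) -> None:
    cfg = result.config
    rows: list[SpeciesModelRow] = []
    for sp_id, cr in result.regions.items():
        s = result.record_sets[sp_id]
        try:
            ts = draw_pseudo_absences(
                cr, s.unique_cells, cfg.pa_n, subseed(cfg.seed, "pa", sp_id)
            )
        except ValueError as err:
            result.skipped[sp_id] = "empty_absence_pool"
            logger.warning("skipping %s: %s", sp_id, err)
            continue
        if min(ts.n_absence, ts.n_presence) < 7:
            # too few cells of one class to stratify into 70/30 replicates
            result.skipped[sp_id] = "degenerate_training_set"
            logger.warning(
                "skipping %s: %d presences / %d absences cannot support "
                "replicate splits", sp_id, ts.n_presence, ts.n_absence,
            )
            continue
        splits = split_replicates(
            ts, cfg.train_fraction, cfg.n_reps, subseed(cfg.seed, "reps", sp_id)
        )
        kept = result.kept_layers[sp_id]
        members: list[EnsembleMember] = []
        for rep, (train, test) in enumerate(splits):
            for algo in cfg.algorithms:
                fit = fit_algorithm(
                    train, result.baseline, kept, algo,
                    seed=subseed(cfg.seed, "fit", sp_id, algo, rep),
                )
                fit.replicate_index = rep
                ev = evaluate(
                    fit.predict_cells(result.baseline, test.presence_cells),
                    fit.predict_cells(result.baseline, test.absence_cells),
                )
                members.append(EnsembleMember(fit=fit, evaluation=ev, test=test))
                contribs = variable_contributions(
                    fit, train, result.baseline,
                    seed=subseed(cfg.seed, "contrib", sp_id, algo, rep),
                )
                top = [c[0] for c in contribs[:2]] + ["", ""]
                rows.append(
                    SpeciesModelRow(
                        species_id=sp_id, algorithm=algo, replicate=rep,
                        auc=ev.auc, tss=ev.tss, tss_threshold=ev.tss_threshold,
                        top_var1=top[0], top_var2=top[1],
                        fallback_used=cr.fallback_used,
                    )
                )
        result.members[sp_id] = members
    result.model_report = pd.DataFrame(
        [dataclasses.asdict(r) for r in rows],
        columns=["species_id", "algorithm", "replicate", "auc", "tss",
                 "tss_threshold", "top_var1", "top_var2", "fallback_used"],
    )


def _stage_ensemble(result: RunResult) -> None:
    cfg = result.config
    present_key = (BASELINE, "T0")
    result.predictions[present_key] = {}
    for stack in result.scenarios:
        result.predictions[(stack.scenario_id, stack.horizon)] = {}
    for sp_id, members in result.members.items():
        cr = result.regions[sp_id]
        try:
            pred = build_ensemble(members, result.baseline, cr, cfg.auc_min)
        except UnmodelableSpeciesError as err:
            result.skipped[sp_id] = "unmodelable"
            logger.warning("species unmodelable: %s", err)
            continue
        result.predictions[present_key][sp_id] = pred
        for stack in result.scenarios:
            result.predictions[(stack.scenario_id, stack.horizon)][sp_id] = project(
                pred.model, stack
            )
        algo_maps = algorithm_consensus_maps(pred.model, result.baseline)
        if len(algo_maps) >= 2:
            _, cv_summary = cv_across_algorithms(list(algo_maps.values()))
            result.cv_by_species[sp_id] = cv_summary
    if not result.predictions[present_key]:
        logger.warning("no species could be modeled; downstream metrics will be empty")


def _stage_metrics(result: RunResult) -> None:
    cfg = result.config
    mask = result.mask
    present_key = (BASELINE, "T0")
    modeled = result.modeled_species
    present_preds = [result.predictions[present_key][sp] for sp in modeled]
    n_cells = cfg.grid.n_cells
    result.pams[present_key] = build_pam(present_preds, n_cells)
    result.richness_maps[present_key] = richness(result.pams[present_key], mask)
    sr_present = result.richness_maps[present_key].sr
    land_cells = np.flatnonzero(mask.land.ravel())

    for stack in result.scenarios:
        key = (stack.scenario_id, stack.horizon)
        preds = [result.predictions[key][sp] for sp in modeled]
        for sp in modeled:
            result.range_records.append(
                range_change(result.predictions[present_key][sp], result.predictions[key][sp])
            )
        pam = build_pam(preds, n_cells)
        result.pams[key] = pam
        rich = richness(pam, mask)
        rich.delta_sr = delta_richness(sr_present, rich.sr)
        result.richness_maps[key] = rich
        bsor_map, _ = temporal_sorensen(result.pams[present_key], pam, land_cells)
        full = np.full(cfg.grid.shape, np.nan)
        rows, cols = cfg.grid.unravel(land_cells)
        full[rows, cols] = bsor_map
        result.bsor_maps[key] = full
        for factor in cfg.psh_factors:
            hs = hotspots(result.richness_maps[present_key], mask, factor, sr_future=rich.sr)
            psh_vals = full[hs.psh_present]
            psh_vals = psh_vals[~np.isnan(psh_vals)]
            hs.median_bsor = float(np.median(psh_vals)) if psh_vals.size else float("nan")
            result.hotspot_results[(factor, *key)] = hs


def _stage_profiles(result: RunResult) -> None:
    cfg = result.config
    land = result.mask.land
    for stack in result.scenarios:
        key = (stack.scenario_id, stack.horizon)
        result.profiles.append(
            scenario_delta_profile(result.baseline, stack, cfg.scenario_delta_variables, land)
        )
        rich = result.richness_maps.get(key)
        if rich is None or rich.delta_sr is None:
            continue
        # valid = cells where richness is defined for some species (union of
        # projected Ms); zeros within that support are included
        valid = np.zeros(cfg.grid.shape, dtype=bool)
        for sp in result.modeled_species:
            pred = result.predictions[key][sp]
            rows, cols = cfg.grid.unravel(pred.cells)
            valid[rows, cols] = True
        try:
            gain_p, loss_p = gain_loss_profiles(
                rich.delta_sr, result.baseline, valid, cfg.gain_loss_variables
            )
        except ValueError as err:
            logger.warning("gain/loss profile skipped for %s: %s", key, err)
            continue
        for prof in (gain_p, loss_p):
            prof.region_label = f"{prof.region_label}:{key[0]}:{key[1]}"
            prof.table["region_label"] = prof.region_label
            result.profiles.append(prof)


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "prep": _stage_prep,
    "model": _stage_model,
    "ensemble": _stage_ensemble,
    "metrics": _stage_metrics,
    "profiles": _stage_profiles,
}


def run_pipeline(config: RunConfig, through: str = "profiles") -> RunResult:
    """Run the pipeline up to and including ``through`` (default: all).

    Returns the in-memory result; if ``config.out_dir`` is set, all tabular
    and raster outputs plus the run manifest are written there.
    """
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; choose from {STAGES}")
    result = RunResult(config=config)
    for stage in STAGES[: STAGES.index(through) + 1]:
        logger.info("stage: %s", stage)
        _STAGE_FUNCS[stage](result)
    result.manifest = build_manifest(result)
    if config.out_dir:
        write_outputs(result, config.out_dir)
    return result


# ---------------------------------------------------------------------------
# manifest, summaries, output files
# ---------------------------------------------------------------------------

def build_manifest(result: RunResult) -> dict:
    import scipy
    import sklearn

    cfg = result.config
    cfg_dict = cfg.to_dict()
    cfg_dict["out_dir"] = None  # environment-specific; keep manifests comparable
    rc = result.range_change_frame()
    medians = {}
    if not rc.empty:
        med = rc.groupby(["scenario", "horizon"])["delta"].median()
        medians = {f"{s}:{h}": float(v) for (s, h), v in med.items()}
    return {
        "versions": {
            "endemia": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
        },
        "config": cfg_dict,
        "counts": {
            "species_generated": len(result.species),
            "species_retained": sum(s.retained for s in result.record_sets.values()),
            "species_modeled": len(result.modeled_species),
            "land_cells": int(result.mask.land.sum()) if result.mask is not None else 0,
        },
        "skipped": dict(sorted(result.skipped.items())),
        "median_range_change": medians,
        "cv_mean": (
            float(np.mean(list(result.cv_by_species.values())))
            if result.cv_by_species else None
        ),
    }


def summarize(result: RunResult) -> dict[str, pd.DataFrame]:
    """Summary tables: medians and complete-loss proportions by country x
    scenario x horizon, PSH extent ratios, and β_SØR medians."""
    rc = result.range_change_frame()
    country = {sp.species_id: sp.country_id for sp in result.species}
    if not rc.empty:
        rc = rc.assign(country_id=rc["species_id"].map(country))
        by_country = (
            rc.groupby(["country_id", "scenario", "horizon"])
            .agg(median_delta=("delta", "median"),
                 complete_loss_proportion=("complete_loss", "mean"),
                 n_species=("species_id", "count"))
            .reset_index()
        )
        overall = (
            rc.groupby(["scenario", "horizon"])
            .agg(median_delta=("delta", "median"),
                 complete_loss_proportion=("complete_loss", "mean"),
                 n_species=("species_id", "count"))
            .reset_index()
        )
    else:
        by_country = pd.DataFrame(
            columns=["country_id", "scenario", "horizon", "median_delta",
                     "complete_loss_proportion", "n_species"])
        overall = pd.DataFrame(
            columns=["scenario", "horizon", "median_delta",
                     "complete_loss_proportion", "n_species"])
    psh_rows = []
    for (factor, scenario, horizon), hs in sorted(result.hotspot_results.items()):
        psh_rows.append(
            {
                "factor": factor,
                "scenario": scenario,
                "horizon": horizon,
                "psh_present_cells": int(hs.psh_present.sum()),
                "psh_future_cells": int(hs.psh_future.sum()) if hs.psh_future is not None else 0,
                "extent_ratio": hs.extent_ratio,
                "median_bsor": hs.median_bsor,
            }
        )
    psh = pd.DataFrame(
        psh_rows,
        columns=["factor", "scenario", "horizon", "psh_present_cells",
                 "psh_future_cells", "extent_ratio", "median_bsor"],
    )
    return {"range_change_by_country": by_country, "range_change_overall": overall, "psh": psh}


def write_outputs(result: RunResult, out_dir) -> None:
    cfg = result.config
    os.makedirs(out_dir, exist_ok=True)
    if result.baseline is not None:
        write_climate_stack(result.baseline, os.path.join(out_dir, "climate"))
        for stack in result.scenarios:
            write_climate_stack(stack, os.path.join(out_dir, "climate"))
    if result.mask is not None:
        write_world_mask(result.mask, os.path.join(out_dir, "world"))
    if result.occurrences:
        write_occurrences(result.occurrences, os.path.join(out_dir, "occurrences.csv"))
        write_species_truth(result.species, os.path.join(out_dir, "species_truth.csv"))
    if result.record_sets:
        pd.DataFrame(
            [
                {
                    "species_id": s.species_id,
                    "n_raw": s.n_raw,
                    "n_unique": int(s.unique_cells.size),
                    "retained": s.retained,
                    "reason": s.exclusion_reason.value,
                }
                for s in result.record_sets.values()
            ]
        ).to_csv(os.path.join(out_dir, "exclusions.csv"), index=False)
    if result.model_report is not None:
        result.model_report.to_csv(os.path.join(out_dir, "model_report.csv"), index=False)
    rc = result.range_change_frame()
    rc.to_csv(os.path.join(out_dir, "range_change.csv"), index=False)
    if not rc.empty:
        counts = (
            rc.groupby(["scenario", "horizon", "category"])
            .size()
            .rename("n_species")
            .reset_index()
        )
        counts.to_csv(os.path.join(out_dir, "category_counts.csv"), index=False)
    raster_dir = os.path.join(out_dir, "rasters")
    os.makedirs(raster_dir, exist_ok=True)
    for (scenario, horizon), rich in result.richness_maps.items():
        write_ascii_grid(
            os.path.join(raster_dir, f"sr_{scenario}_{horizon}.asc"),
            cfg.grid, rich.sr.astype(float),
        )
        if rich.delta_sr is not None:
            write_ascii_grid(
                os.path.join(raster_dir, f"dsr_{scenario}_{horizon}.asc"),
                cfg.grid, rich.delta_sr.astype(float),
            )
    for (scenario, horizon), bsor in result.bsor_maps.items():
        write_ascii_grid(
            os.path.join(raster_dir, f"bsor_{scenario}_{horizon}.asc"), cfg.grid, bsor
        )
    summaries = summarize(result)
    summaries["psh"].to_csv(os.path.join(out_dir, "psh_extent.csv"), index=False)
    summaries["range_change_by_country"].to_csv(
        os.path.join(out_dir, "summary_range_change_by_country.csv"), index=False
    )
    summaries["range_change_overall"].to_csv(
        os.path.join(out_dir, "summary_range_change_overall.csv"), index=False
    )
    if result.profiles:
        pd.concat([p.table for p in result.profiles], ignore_index=True).to_csv(
            os.path.join(out_dir, "profiles.csv"), index=False
        )
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
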