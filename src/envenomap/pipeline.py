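"""End-to-end orchestration: thin → background → table → VIF → fit →
evaluate → predict → binarize → distance → vulnerability → combine → index.

Every stage draws its randomness from a seed derived from the master
seed, so a rerun with the same config reproduces byte-identical outputs
(the manifest records per-stage seeds and output checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geodata, models, occurrences, predictors, vulnerability
from .config import RunConfig, stage_seed

logger = logging.getLogger(__name__)


@dataclass
class SpeciesResult:
    species: str
    n_raw: int
    n_thinned: int
    n_background: int
    vif_report: predictors.VifReport
    eval_result: models.EvalResult
    suitability: models.SuitabilityMap
    binary: models.BinaryMap
    vulnerability: vulnerability.VulnerabilityMap


@dataclass
class RunManifest:
    config: dict
    stage_seeds: dict
    species: list[str]
    artifacts: dict  # relative path -> sha256
    summaries: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "stage_seeds": self.stage_seeds,
                "species": self.species,
                "artifacts": self.artifacts,
                "summaries": self.summaries,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_species(
    species: str,
    occ_df: pd.DataFrame,
    env: geodata.EnvStack,
    ecoregions: geodata.Raster,
    cfg: RunConfig,
    distance: geodata.Raster,
) -> SpeciesResult:
    """All modelling stages for one species."""
    seeds = {
        stage: stage_seed(cfg.master_seed, stage, species)
        for stage in ("thin", "background", "fit", "evaluate")
    }
    pts = geodata.occurrences_to_pointset(occ_df, species, env.grid.crs_tag)
    occ = occurrences.OccurrenceSet(species, pts)
    n_raw = len(occ)
    occ = occurrences.thin_occurrences(occ, cfg.min_dist_km, seed=seeds["thin"])
    labels = occurrences.occupied_ecoregions(occ, ecoregions)
    bg = occurrences.generate_pseudo_absences(
        ecoregions, labels, occ, n=cfg.n_background,
        seed=seeds["background"], allow_presence_cells=cfg.allow_presence_cells,
    )
    table = occurrences.assemble_training_table(occ, bg, env)

    vif_report = predictors.stepwise_vif_select(
        table.df[table.layer_names], threshold=cfg.vif_threshold
    )
    if vif_report.dropped:
        logger.info(
            "%s: VIF selection dropped %s", species, [n for n, _ in vif_report.dropped]
        )
    table = table.subset_layers(vif_report.retained)
    env_used = env.subset(vif_report.retained)

    specs = [
        models.AlgorithmSpec(name, cfg.hyperparameters.get(name, {}))
        for name in cfg.algorithms
    ]
    eval_result = models.repeated_split_evaluate(
        specs, table, n_reps=cfg.n_reps, train_frac=cfg.train_fraction,
        seed=seeds["evaluate"],
    )
    fitted = [models.fit_algorithm(sp, table, seed=seeds["fit"]) for sp in specs]
    if cfg.ensemble_weighting == "auc":
        per_member = [
            models.repeated_split_evaluate(
                sp, table, n_reps=cfg.n_reps, train_frac=cfg.train_fraction,
                seed=seeds["evaluate"],
            ).mean_auc
            for sp in specs
        ]
        weights = np.asarray(per_member)
    else:
        weights = None
    suit = models.ensemble_predict(
        fitted, env_used, weights=weights, species=species,
        weighting=cfg.ensemble_weighting,
    )
    binary = models.binarize(suit, table)
    vmap = vulnerability.species_vulnerability(binary, distance)
    return SpeciesResult(
        species=species,
        n_raw=n_raw,
        n_thinned=len(occ),
        n_background=len(bg.points),
        vif_report=vif_report,
        eval_result=eval_result,
        suitability=suit,
        binary=binary,
        vulnerability=vmap,
    )


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute the full per-species and combined workflow from a config."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    env = geodata.read_env_stack(cfg.env_path)
    ecoregions = geodata.read_raster(cfg.ecoregions_path)
    if ecoregions.grid != env.grid:
        raise geodata.GridMismatchError("ecoregion raster is not co-registered with the predictor stack")
    cities = geodata.read_points(cfg.cities_path, crs_tag=env.grid.crs_tag)
    occ_df = geodata.read_occurrences(cfg.occurrences_path)
    species_list = cfg.species or sorted(occ_df["species"].unique())

    distance = geodata.distance_to_points_raster(env.grid, cities, mask=env.combined_mask)
    geodata.write_raster(out / "distance_to_city.tif", distance, name="distance_km")

    results: list[SpeciesResult] = []
    summaries: dict = {}
    for sp in species_list:
        logger.info("running species %s", sp)
        try:
            res = run_species(sp, occ_df, env, ecoregions, cfg, distance)
        except Exception as exc:
            raise RuntimeError(f"stage failure for species {sp!r}: {exc}") from exc
        results.append(res)
        tag = sp.replace(" ", "_")
        geodata.write_raster(out / f"suitability_{tag}.tif", res.suitability.raster, name="suitability")
        geodata.write_raster(out / f"binary_{tag}.tif", res.binary.raster, name="binary")
        geodata.write_raster(out / f"vulnerability_{tag}.tif", res.vulnerability.raster, name="vulnerability")
        (out / f"evaluation_{tag}.json").write_text(
            json.dumps(res.eval_result.to_dict(), indent=2, sort_keys=True)
        )
        summaries[sp] = {
            "n_records_raw": res.n_raw,
            "n_records_thinned": res.n_thinned,
            "n_background": res.n_background,
            "vif": res.vif_report.to_dict(),
            "mean_auc": res.eval_result.mean_auc,
            "mean_tss": res.eval_result.mean_tss,
            "binarization_threshold": res.binary.threshold,
        }

    combined = vulnerability.combined_vulnerability(
        [r.binary for r in results], distance, mode=cfg.exposure_definition
    )
    geodata.write_raster(out / "vulnerability_combined.tif", combined.raster, name="vulnerability")
    index = vulnerability.extract_index(combined)
    index.records.to_csv(out / "vulnerability_index.csv", index=False)
    summaries["combined"] = {
        "exposure_definition": combined.exposure_definition,
        "index_summary": index.summary,
    }

    artifacts = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.suffix in (".tif", ".csv", ".json") and p.name != "manifest.json"
    }
    stage_seeds = {
        sp: {
            stage: stage_seed(cfg.master_seed, stage, sp)
            for stage in ("thin", "background", "fit", "evaluate")
        }
        for sp in species_list
    }
    manifest = RunManifest(
        config=cfg.to_dict(),
        stage_seeds=stage_seeds,
        species=list(species_list),
        artifacts=artifacts,
        summaries=summaries,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
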