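"""End-to-end orchestration: simulate -> prep -> ordination -> overlap
tests -> reciprocal suitability models -> physiology links.

A run is configured by a :class:`RunConfig` (loadable from YAML) and
produces a directory with cleaned occurrences, rasters, a comparison
JSON, suitability summaries, link-model results, a manifest recording
every seed and a hash of the numeric outputs, and a human-readable
summary.  Reruns with the same config produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .env_space import calibrate_env_space, grid_extent, occupancy_grid
from .niche import equivalence_test, niche_dynamics, schoener_d, similarity_test
from .occurrences import OccurrenceSet, thin_occurrences
from .performance import link_classification, link_regression, performance_curve
from .sdm import fit_suitability, increased_suitability, increased_suitability_ensemble, project
from .synthetic import ScenarioConfig, generate_phys_table, make_shift_scenario

logger = logging.getLogger("nicheshift")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    min_dist_km: float = 1.0
    R: int = 100
    n_iter: int = 1000
    analog_levels: tuple[float, ...] = (1.0, 0.75)
    support_mass: float = 0.99
    folds: int = 5
    n_background: int = 10_000
    l1_penalty: Optional[float] = None
    bins: int = 20
    n_phys_per_range: int = 6
    do_compare: bool = True
    do_sdm: bool = True
    do_link: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scenario = ScenarioConfig(**raw.pop("scenario", {}))
        known = {f.name for f in dc_fields(cls)} - {"scenario"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(scenario=scenario, **raw)
        if cfg.n_iter < 99:
            raise ValueError("n_iter must be at least 99")
        return cfg

    def to_dict(self) -> dict:
        out = {
            f.name: getattr(self, f.name)
            for f in dc_fields(self)
            if f.name != "scenario"
        }
        out["analog_levels"] = list(self.analog_levels)
        out["scenario"] = self.scenario.to_dict()
        return out


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the configured stages, writing the report bundle to ``outdir``.

    Returns a dictionary of the main results.  A stage failure raises
    :class:`PipelineError` naming the stage; outputs of completed stages
    remain on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    seed = config.scenario.seed
    stage = "simulate"
    t0 = time.time()
    try:
        logger.info("stage simulate: generating scenario (seed=%d)", seed)
        scen = make_shift_scenario(config.scenario)
        scen.grid_native.to_ascii_dir(outdir / "rasters" / "native")
        scen.grid_introduced.to_ascii_dir(outdir / "rasters" / "introduced")
        occ_all = OccurrenceSet.concat([scen.occ_native, scen.occ_introduced])
        occ_all.to_csv(outdir / "occurrences_raw.csv")

        stage = "prep"
        logger.info("stage prep: thinning at %.2f km", config.min_dist_km)
        occ_nat = thin_occurrences(scen.occ_native, config.min_dist_km)
        occ_int = thin_occurrences(scen.occ_introduced, config.min_dist_km)
        OccurrenceSet.concat([occ_nat, occ_int]).to_csv(
            outdir / "occurrences_clean.csv"
        )
        _write_json(
            outdir / "cleaning_report.json",
            {"native": occ_nat.report, "introduced": occ_int.report},
        )
        results["n_occ_native"] = len(occ_nat)
        results["n_occ_introduced"] = len(occ_int)

        stage = "space"
        bg_nat = scen.grid_native.env_table()
        bg_int = scen.grid_introduced.env_table()
        space = calibrate_env_space(bg_nat, bg_int)
        space.loadings_.to_csv(outdir / "pca_loadings.csv")
        results["explained_variance"] = space.explained_variance_ratio_.tolist()

        z_nat = z_int = None
        if config.do_compare:
            stage = "compare"
            logger.info("stage compare: occupancy grids and permutation tests")
            extent = grid_extent(
                np.vstack([space.transform(bg_nat), space.transform(bg_int)])
            )
            z_nat = occupancy_grid(space, occ_nat, bg_nat, config.R, extent)
            z_int = occupancy_grid(space, occ_int, bg_int, config.R, extent)
            np.savez_compressed(
                outdir / "occupancy.npz",
                z_native=z_nat.z,
                z_introduced=z_int.z,
                e_native=z_nat.e,
                e_introduced=z_int.e,
            )
            comparison = {
                "D_corrected": schoener_d(z_nat, z_int, corrected=True),
                "D_uncorrected": schoener_d(z_nat, z_int, corrected=False),
                "dynamics": {},
                "seed": seed,
                "n_iter": config.n_iter,
            }
            for level in config.analog_levels:
                dyn = niche_dynamics(
                    z_nat, z_int, analog_level=level, support_mass=config.support_mass
                )
                comparison["dynamics"][f"analog_{level:.2f}"] = dyn.to_dict()
            eq = equivalence_test(
                occ_nat, occ_int, space, bg_nat, bg_int,
                n_iter=config.n_iter, seed=[seed, 10], R=config.R,
            )
            sim_ni = similarity_test(
                occ_nat, occ_int, space, bg_nat, bg_int,
                n_iter=config.n_iter, seed=[seed, 11], R=config.R,
            )
            sim_in = similarity_test(
                occ_int, occ_nat, space, bg_int, bg_nat,
                n_iter=config.n_iter, seed=[seed, 12], R=config.R,
            )
            comparison["equivalence"] = eq.to_dict()
            comparison["similarity_native_vs_introduced"] = sim_ni.to_dict()
            comparison["similarity_introduced_vs_native"] = sim_in.to_dict()
            _write_json(outdir / "comparison.json", comparison)
            results["comparison"] = comparison

        if config.do_sdm:
            stage = "sdm"
            logger.info("stage sdm: reciprocal suitability models")
            model_nat = fit_suitability(
                occ_nat, scen.grid_native, config.n_background,
                config.l1_penalty, config.folds, seed=seed + 100,
            )
            model_int = fit_suitability(
                occ_int, scen.grid_introduced, config.n_background,
                config.l1_penalty, config.folds, seed=seed + 101,
            )
            map_nat_on_int = project(model_nat, scen.grid_introduced)
            map_int_on_int = project(model_int, scen.grid_introduced)
            np.savez_compressed(
                outdir / "suitability.npz",
                native_model_on_introduced=map_nat_on_int.delta,
                introduced_model_on_introduced=map_int_on_int.delta,
            )
            ens = increased_suitability_ensemble(
                model_int, model_nat, scen.grid_introduced
            )
            sdm_out = {
                "increased_suitability_pct": increased_suitability(
                    map_int_on_int, map_nat_on_int
                ),
                "increased_suitability_ensemble_mean": ens.mean,
                "increased_suitability_ensemble_sem": ens.sem,
                "cv_auc_native": model_nat.cv_auc_.tolist(),
                "cv_auc_introduced": model_int.cv_auc_.tolist(),
                "lambda_native": model_nat.lambda_,
                "lambda_introduced": model_int.lambda_,
                "n_novel_cells_native_model": map_nat_on_int.n_novel,
            }
            _write_json(outdir / "sdm.json", sdm_out)
            results["sdm"] = sdm_out

        if config.do_link:
            stage = "link"
            logger.info("stage link: physiology-performance models")
            markers = generate_phys_table(
                n_per_range=config.n_phys_per_range, seed=[seed, 20]
            )
            markers.to_csv(outdir / "markers.csv", index=False)
            occ_both = OccurrenceSet.concat([occ_nat, occ_int])
            perf = performance_curve(occ_both, bins=config.bins)
            perf.performance.to_csv(outdir / "performance.csv", index=False)
            cls = link_classification(markers, seed=seed + 200)
            link_out = {
                "classification": cls.to_dict(),
                "regression": {},
            }
            for label in ("native", "introduced"):
                reg = link_regression(markers, perf, label, seed=seed + 201)
                link_out["regression"][label] = reg.to_dict()
            _write_json(outdir / "link.json", link_out)
            results["link"] = link_out
    except Exception as exc:  # noqa: BLE001 - stage context is the point
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage_time = time.time() - t0
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": seed,
        "runtime_s": round(stage_time, 2),
    }
    canonical = json.dumps(
        {"config": manifest["config"], "results": results},
        sort_keys=True,
        default=_jsonify,
    )
    manifest["results_hash"] = hashlib.sha256(canonical.encode()).hexdigest()
    _write_json(outdir / "manifest.json", manifest)
    _write_summary(outdir / "summary.txt", results)
    return results


def _write_summary(path: Path, results: dict) -> None:
    lines = ["nicheshift run summary", "=" * 30]
    lines.append(
        f"occurrences after thinning: native={results.get('n_occ_native')}, "
        f"introduced={results.get('n_occ_introduced')}"
    )
    comp = results.get("comparison")
    if comp:
        lines.append(f"Schoener's D (corrected): {comp['D_corrected']:.3f}")
        lines.append(f"Schoener's D (uncorrected): {comp['D_uncorrected']:.3f}")
        for key, dyn in comp["dynamics"].items():
            lines.append(
                f"dynamics {key}: expansion={dyn['expansion']:.3f} "
                f"stability={dyn['stability']:.3f} unfilling={dyn['unfilling']:.3f}"
            )
        lines.append(f"equivalence p = {comp['equivalence']['p_value']:.4f}")
        lines.append(
            "similarity p (native vs introduced) = "
            f"{comp['similarity_native_vs_introduced']['p_value']:.4f}"
        )
    sdm = results.get("sdm")
    if sdm:
        lines.append(
            "increased introduced suitability: "
            f"{sdm['increased_suitability_ensemble_mean']:.2f}% "
            f"+/- {sdm['increased_suitability_ensemble_sem']:.2f}"
        )
    link = results.get("link")
    if link:
        for label, reg in link["regression"].items():
            lines.append(
                f"RF regression ({label}): explained variance = "
                f"{reg['explained_variance_pct']:.1f}%"
            )
    path.write_text("\n".join(lines) + "\n")
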