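"""Configuration-driven orchestration of all analysis stages.

A single YAML file drives the pipeline: simulate -> traj-analyze -> saxs-fit
-> epr -> afm.  Unknown configuration keys are rejected (pydantic,
``extra='forbid'``).  One global seed fans out to per-stage seeds through
``numpy.random.SeedSequence([global_seed, stage_index])`` with the stage
indices fixed below, so a rerun with the same configuration produces
byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import afm as afm_mod
from . import analysis, epr as epr_mod, saxs as saxs_mod, synthetic, trajio

logger = logging.getLogger("membrane_probe.pipeline")

STAGE_ORDER = ("simulate", "traj_analyze", "saxs_fit", "epr", "afm")
_STAGE_INDEX = {name: i for i, name in enumerate(STAGE_ORDER)}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_INDEX[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


class _Forbid(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PatchConfig(_Forbid):
    center_xy: tuple[float, float] = (5.0, 5.0)
    radius: float = 1.5
    head_plane_offset_inside: float = 1.35


class AggregateConfig(_Forbid):
    n_dda: int = 8
    center_xy: tuple[float, float] = (5.0, 5.0)
    lateral_sigma: float = 0.8
    carboxyl_pairing: float = 1.0
    z_span: float = 2.4


class WireConfig(_Forbid):
    n_waters: int = 9
    spacing: float = 0.28
    endpoints_z: tuple[float, float] = (-1.12, 1.12)


class WaterConfig(_Forbid):
    count: int = 200
    slab_bounds: tuple[float, float] = (2.2, 3.0)
    wire: Optional[WireConfig] = None


class SimulateConfig(_Forbid):
    lipids_per_leaflet: int = 64
    lateral_box: tuple[float, float] = (10.0, 10.0)
    head_plane_offset: float = 1.85
    beads_per_lipid: int = 11
    bead_spacing: float = 0.12
    positional_jitter_sigma: float = 0.05
    n_frames: int = 5
    patch: Optional[PatchConfig] = None
    aggregate: Optional[AggregateConfig] = None
    water: Optional[WaterConfig] = None
    flavonoid_count: int = 0
    trajectory_format: str = "xyz"
    saxs_noise_fraction: float = 0.01
    afm_modulus_pa: float = 2.0e7
    afm_breakthrough: tuple[float, float] = (200.0, 4.0)
    afm_noise_pn: float = 5.0
    heightmap_shape: tuple[int, int] = (64, 64)
    heightmap_sigma_nm: float = 0.3


class TrajAnalyzeConfig(_Forbid):
    trajectory: Optional[str] = None  # defaults to the simulate output
    thickness_cell: float = 0.5
    hbond_da_cutoff: float = analysis.DEFAULT_DA_CUTOFF
    hbond_angle_min: float = analysis.DEFAULT_ANGLE_MIN
    water_z_cut: float = 1.0
    water_oo_cutoff: float = 0.35
    density_bin_width: float = 0.1


class SAXSFitConfig(_Forbid):
    curve: Optional[str] = None
    q_min: float = 0.5
    q_max: float = 2.5
    n_layers: int = 1


class EPRConfig(_Forbid):
    table: Optional[str] = None
    use_example_table: bool = True


class AFMConfig(_Forbid):
    force_curve: Optional[str] = None
    height_map: Optional[str] = None
    n_regions: int = 4
    region_size: Optional[int] = None


class PipelineConfig(_Forbid):
    seed: int = 0
    outdir: str = "runs/demo"
    stages: list[str] = list(STAGE_ORDER)
    simulate: SimulateConfig = SimulateConfig()
    traj_analyze: TrajAnalyzeConfig = TrajAnalyzeConfig()
    saxs_fit: SAXSFitConfig = SAXSFitConfig()
    epr: EPRConfig = EPRConfig()
    afm: AFMConfig = AFMConfig()


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def _bilayer_spec(cfg: SimulateConfig, seed: int) -> synthetic.BilayerSpec:
    return synthetic.BilayerSpec(
        lipids_per_leaflet=cfg.lipids_per_leaflet,
        lateral_box=cfg.lateral_box,
        head_plane_offset=cfg.head_plane_offset,
        beads_per_lipid=cfg.beads_per_lipid,
        bead_spacing=cfg.bead_spacing,
        positional_jitter_sigma=cfg.positional_jitter_sigma,
        patch=synthetic.ThinPatchSpec(**cfg.patch.model_dump()) if cfg.patch else None,
        aggregate=synthetic.AggregateSpec(**cfg.aggregate.model_dump()) if cfg.aggregate else None,
        water=synthetic.WaterSpec(
            count=cfg.water.count,
            slab_bounds=cfg.water.slab_bounds,
            wire=synthetic.WireSpec(**cfg.water.wire.model_dump()) if cfg.water.wire else None,
        ) if cfg.water else None,
        flavonoid_count=cfg.flavonoid_count,
        seed=seed,
    )


def run_simulate(cfg: SimulateConfig, seed: int, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    spec = _bilayer_spec(cfg, seed)
    traj = synthetic.build_trajectory(spec, n_frames=cfg.n_frames)
    traj_path = outdir / f"trajectory.{cfg.trajectory_format}"
    trajio.write_trajectory(traj, traj_path)
    with open(outdir / "trajectory.manifest.json", "w") as fh:
        json.dump(traj.metadata, fh, indent=2, sort_keys=True)

    curve = synthetic.generate_saxs_curve(synthetic.SAXSGenSpec(
        noise_fraction=cfg.saxs_noise_fraction, seed=seed))
    saxs_mod.write_saxs_curve(curve, outdir / "saxs_curve.dat")

    synthetic.generate_epr_table(
        [(name, par, perp) for name, par, perp, _s, _t in epr_mod.EXAMPLE_5DSA_TABLE],
        path=outdir / "epr_table.csv")

    fc = synthetic.generate_force_curve(
        modulus=cfg.afm_modulus_pa, breakthrough=cfg.afm_breakthrough,
        noise=cfg.afm_noise_pn, seed=seed)
    afm_mod.write_force_curve(fc, outdir / "force_curve.dat")

    hm = synthetic.generate_height_map(
        cfg.heightmap_shape, synthetic.GaussianRoughness(cfg.heightmap_sigma_nm), seed=seed)
    afm_mod.write_height_map(hm, outdir / "height_map.dat")
    return {
        "trajectory": str(traj_path),
        "manifest": str(outdir / "trajectory.manifest.json"),
        "saxs_curve": str(outdir / "saxs_curve.dat"),
        "epr_table": str(outdir / "epr_table.csv"),
        "force_curve": str(outdir / "force_curve.dat"),
        "height_map": str(outdir / "height_map.dat"),
        "n_particles": traj[0].n_particles,
        "n_frames": len(traj),
    }


def run_traj_analyze(cfg: TrajAnalyzeConfig, outdir: Path, traj_path: str | None = None) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    path = cfg.trajectory or traj_path
    if path is None:
        raise ValueError("no trajectory available: set traj_analyze.trajectory or run simulate")
    traj = trajio.read_trajectory(path)
    summary: dict = {"trajectory": str(path), "n_frames": len(traj)}

    tmap = analysis.interleaflet_distance_map(traj, cell=cfg.thickness_cell)
    pd.DataFrame(tmap.distance, index=np.round(tmap.x_centers, 4),
                 columns=np.round(tmap.y_centers, 4)).to_csv(outdir / "thickness_map.tsv", sep="\t")
    summary["thickness_mean_nm"] = float(np.nanmean(tmap.distance))

    prof = analysis.electron_density_profile(traj, bin_width=cfg.density_bin_width)
    pd.DataFrame({"z_nm": prof.bin_centers, "electron_density_e_nm3": prof.values}).to_csv(
        outdir / "electron_density.tsv", sep="\t", index=False)

    crit = analysis.HBondCriteria(da_cutoff=cfg.hbond_da_cutoff, angle_min=cfg.hbond_angle_min)
    fams = set(traj[0].molecule_family().values())
    if "dda" in fams:
        stats = analysis.hbond_statistics(traj, crit)
        summary["dda_hbonds_mean"] = stats.mean
        summary["dda_hbonds_sd"] = stats.sd
        clusters = analysis.molecule_clusters(traj[0], "dda", "hbond", criteria=crit)
        summary["dda_largest_cluster"] = int(clusters.sizes[0])
        summary["dda_largest_z_span_nm"] = clusters.largest_z_span
    if "water" in fams:
        wrep = analysis.water_analysis(traj, z_cut=cfg.water_z_cut, oo_cutoff=cfg.water_oo_cutoff)
        summary["penetrating_waters_per_frame"] = wrep.penetrating_waters.tolist()
        summary["wire_present_fraction"] = float(wrep.wire_present.mean())
    with open(outdir / "traj_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def run_saxs_fit(cfg: SAXSFitConfig, outdir: Path, curve_path: str | None = None) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    path = cfg.curve or curve_path
    if path is None:
        raise ValueError("no SAXS curve available: set saxs_fit.curve or run simulate")
    curve = saxs_mod.read_saxs_curve(path)
    fit = saxs_mod.fit_saxs(curve, mct0=saxs_mod.MCTParams(n_layers=cfg.n_layers),
                            q_window=(cfg.q_min, cfg.q_max))
    saxs_mod.save_fit(fit, outdir / "saxs_fit.json")
    profiles, desc = saxs_mod.edp_report([fit], ["fitted"])
    profiles.to_csv(outdir / "edp_profile.tsv", sep="\t", index=False)
    desc.to_csv(outdir / "edp_descriptors.tsv", sep="\t")
    return {"success": fit.success, "redchi": fit.redchi,
            "R": list(fit.edp.R), "rho": list(fit.edp.rho), "sigma": list(fit.edp.sigma)}


def run_epr(cfg: EPRConfig, outdir: Path, table_path: str | None = None) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    path = cfg.table or table_path
    if path is not None:
        df = epr_mod.read_epr_table(path)
    elif cfg.use_example_table:
        df = synthetic.generate_epr_table(
            [(n, p, q) for n, p, q, _s, _t in epr_mod.EXAMPLE_5DSA_TABLE])
    else:
        raise ValueError("no EPR table available")
    out = epr_mod.process_table(df)
    out.to_csv(outdir / "epr_results.tsv", sep="\t", index=False)
    return {"samples": out["sample"].tolist(), "S": out["S"].round(6).tolist()}


def run_afm(cfg: AFMConfig, seed: int, outdir: Path,
            curve_path: str | None = None, map_path: str | None = None) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    cpath = cfg.force_curve or curve_path
    if cpath is not None:
        curve = afm_mod.read_force_curve(cpath)
        bt = afm_mod.detect_breakthrough(curve)
        if bt is not None:
            summary["yield_force_pN"] = bt.yield_force
            summary["thickness_nm"] = bt.thickness
        fit = afm_mod.fit_modulus(curve)
        summary["youngs_modulus_Pa"] = fit.modulus
    mpath = cfg.height_map or map_path
    if mpath is not None:
        hmap = afm_mod.read_height_map(mpath)
        rep = afm_mod.roughness(hmap, n_regions=cfg.n_regions,
                                region_size=cfg.region_size, seed=seed)
        summary["r_a_nm"] = {"mean": rep.r_a_mean, "se": rep.r_a_se, "n": len(rep.r_a)}
        summary["rms_nm"] = {"mean": rep.rms_mean, "se": rep.rms_se, "n": len(rep.rms)}
        pd.DataFrame({"region": range(len(rep.r_a)), "r_a_nm": rep.r_a, "rms_nm": rep.rms}).to_csv(
            outdir / "roughness.tsv", sep="\t", index=False)
    if not summary:
        raise ValueError("no AFM inputs available")
    with open(outdir / "afm_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def run_pipeline(config: PipelineConfig | dict, outdir: str | None = None) -> dict:
    """Execute the requested stages in order and write a combined report.

    Per-stage failures are isolated: the report records each stage's status
    and the function raises at the end if any stage failed.
    """
    if isinstance(config, dict):
        config = PipelineConfig(**config)
    base = Path(outdir if outdir is not None else config.outdir)
    base.mkdir(parents=True, exist_ok=True)
    unknown_stages = set(config.stages) - set(STAGE_ORDER)
    if unknown_stages:
        raise ValueError(f"unknown stages: {sorted(unknown_stages)}")
    report: dict = {"seed": config.seed, "stages": {}}
    artefacts: dict = {}
    failed = []
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        sdir = base / stage
        seed = stage_seed(config.seed, stage)
        logger.info("stage %s (seed %d)", stage, seed)
        try:
            if stage == "simulate":
                result = run_simulate(config.simulate, seed, sdir)
                artefacts.update(result)
            elif stage == "traj_analyze":
                result = run_traj_analyze(config.traj_analyze, sdir, artefacts.get("trajectory"))
            elif stage == "saxs_fit":
                result = run_saxs_fit(config.saxs_fit, sdir, artefacts.get("saxs_curve"))
            elif stage == "epr":
                result = run_epr(config.epr, sdir, artefacts.get("epr_table"))
            else:
                result = run_afm(config.afm, seed, sdir,
                                 artefacts.get("force_curve"), artefacts.get("height_map"))
            report["stages"][stage] = {"status": "ok", "seed": seed, "result": result}
        except Exception as exc:  # noqa: BLE001 - per-stage isolation is the contract
            logger.error("stage %s failed: %s", stage, exc)
            report["stages"][stage] = {"status": "failed", "seed": seed, "error": str(exc)}
            failed.append(stage)
    with open(base / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    if failed:
        raise RuntimeError(f"pipeline stages failed: {failed} (see {base / 'report.json'})")
    return report
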