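"""End-to-end pipeline: simulate -> detect -> localize -> quantify.

The pipeline is driven by a validated :class:`RunConfig` (YAML on
disk).  ``run_simulate`` writes one scene directory per condition x
replicate; ``run_full`` additionally detects wells, localizes nuclei,
computes per-scene summaries, runs the paired stencil/no-stencil
significance tests and writes a run manifest listing every output with
the configuration hash, so identical configs reproduce identical
summary tables byte for byte.

The in-memory core, :func:`analyze_scene`, is also the building block
for programmatic use without any file I/O.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .conditions import SeedingCondition, condition_defaults
from .detect import (
    DEFAULT_N_SAMPLE,
    DEFAULT_NCC_THRESHOLD,
    DEFAULT_NMS_FACTOR,
    WellDetectionSet,
    detect_wells,
    ncc_map,
    sample_wells,
    synthesize_template,
)
from .errors import ConfigError, UndefinedStatisticError
from .layout import ArrayLayout, build_layout
from .nuclei import (
    NucleusParams,
    assign_nearest_well,
    classify_location,
    detect_nuclei,
)
from .scene import ImageSet, Optics, SceneGroundTruth, render_scene, sample_cells
from .sceneio import read_scene, write_scene
from .seeds import derive_seed
from .stats import (
    PatterningSummary,
    localization_efficiency,
    mann_whitney_u,
    occupancy_distribution,
    students_t,
    viability,
)

log = logging.getLogger("wellpat")


# --------------------------------------------------------------------------
# configuration schema
# --------------------------------------------------------------------------

class LayoutConfig(BaseModel):
    footprint_um: tuple[float, float] = (9000.0, 9000.0)
    pitch_um: float = 120.0
    inner_radius_um: float = 40.0
    outer_radius_um: float = 60.0
    pixel_scale_um_per_px: float = 1.625
    target_well_count: Optional[int] = 2980

    def build(self) -> ArrayLayout:
        return build_layout(
            footprint_um=self.footprint_um,
            pitch_um=self.pitch_um,
            inner_radius_um=self.inner_radius_um,
            outer_radius_um=self.outer_radius_um,
            pixel_scale_um_per_px=self.pixel_scale_um_per_px,
            target_well_count=self.target_well_count,
        )


class ConditionConfig(BaseModel):
    cell_line: str
    density_k_per_mL: int
    stencil: bool = True
    # overrides; None -> cell-line defaults
    p_interior: Optional[float] = None
    dead_fraction: Optional[float] = None
    occupancy_dist: Optional[dict[int, float]] = None
    poisson_lambda: Optional[float] = None

    def build(self, seed: int | None = None) -> SeedingCondition:
        cond = condition_defaults(
            self.cell_line, self.density_k_per_mL, self.stencil, seed=seed
        )
        overrides = {}
        if self.p_interior is not None:
            overrides["p_interior"] = self.p_interior
        if self.dead_fraction is not None:
            overrides["dead_fraction"] = self.dead_fraction
        if self.occupancy_dist is not None:
            overrides["occupancy_dist"] = self.occupancy_dist
            overrides["poisson_lambda"] = None
        elif self.poisson_lambda is not None:
            overrides["poisson_lambda"] = self.poisson_lambda
            overrides["occupancy_dist"] = None
        if overrides:
            import dataclasses

            cond = dataclasses.replace(cond, **overrides)
        return cond


class DetectionConfig(BaseModel):
    ncc_threshold: float = Field(DEFAULT_NCC_THRESHOLD, gt=0.0, lt=1.0)
    nms_factor: float = Field(DEFAULT_NMS_FACTOR, gt=0.0, le=1.0)
    n_sample: int = Field(DEFAULT_N_SAMPLE, ge=1)


class NucleiConfig(BaseModel):
    nucleus_radius_um: float = 7.0
    min_area_factor: float = 0.25
    max_area_factor: float = 4.0
    split_touching: bool = True

    def build(self) -> NucleusParams:
        return NucleusParams(
            nucleus_radius_um=self.nucleus_radius_um,
            min_area_factor=self.min_area_factor,
            max_area_factor=self.max_area_factor,
            split_touching=self.split_touching,
        )


class OpticsConfig(BaseModel):
    psf_sigma_um: float = 2.0
    nucleus_radius_um: float = 7.0
    read_noise_frac: float = 0.02
    shot_noise: bool = True
    bit_depth: int = 16
    noise: bool = True

    def build(self) -> Optics:
        return Optics(
            psf_sigma_um=self.psf_sigma_um,
            nucleus_radius_um=self.nucleus_radius_um,
            read_noise_frac=self.read_noise_frac,
            shot_noise=self.shot_noise,
            bit_depth=self.bit_depth,
        )


class RunConfig(BaseModel):
    layout: LayoutConfig = LayoutConfig()
    conditions: list[ConditionConfig]
    replicates: int = Field(3, ge=1)
    detection: DetectionConfig = DetectionConfig()
    nuclei: NucleiConfig = NucleiConfig()
    optics: OpticsConfig = OpticsConfig()
    master_seed: int = 1
    out_dir: str = "wellpat_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            return cls.model_validate(raw)
        except ValidationError as e:  # re-raise with field paths, stable type
            raise ConfigError(str(e)) from e

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def paper_repro_config(master_seed: int = 1, out_dir: str = "wellpat_run") -> RunConfig:
    """The default study design: 3 cell lines x {stencil, open} x 4 densities.

    The K562 open-substrate arm is included but flagged no-data by the
    condition defaults (non-adherent line).
    """
    conds = [
        ConditionConfig(cell_line=line, density_k_per_mL=d, stencil=st)
        for line in ("K562", "HME1", "MDA-MB-231")
        for st in (True, False)
        for d in (25, 50, 100, 200)
    ]
    return RunConfig(conditions=conds, master_seed=master_seed, out_dir=out_dir)


# --------------------------------------------------------------------------
# in-memory pipeline
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneAnalysis:
    """Everything the pipeline derives from one scene."""

    summary: PatterningSummary
    detections: WellDetectionSet
    assignment_all: pd.DataFrame
    assignment_dead: pd.DataFrame


def simulate_scene(
    layout: ArrayLayout,
    condition: SeedingCondition,
    optics: Optics = Optics(),
    seed: int = 0,
    noise: bool = True,
    render_live_cyto: bool = True,
) -> tuple[ImageSet, SceneGroundTruth]:
    """Sample cells and render one scene from per-stage substreams."""
    gt = sample_cells(layout, condition, rng=derive_seed(seed, "sample"))
    images = render_scene(
        layout,
        gt,
        optics,
        rng=derive_seed(seed, "render"),
        noise=noise,
        render_live_cyto=render_live_cyto,
    )
    return images, gt


def analyze_scene(
    images: ImageSet,
    layout: ArrayLayout,
    detection: DetectionConfig = DetectionConfig(),
    nuclei_params: NucleusParams = NucleusParams(),
    optics: Optics = Optics(),
    seed: int = 0,
    condition_name: str = "scene",
) -> SceneAnalysis:
    """Detect wells, sample the analysis subset, localize nuclei, summarize."""
    template = synthesize_template(layout, optics)
    scores = ncc_map(images.phase, template.raster)
    detections = detect_wells(
        scores,
        layout,
        ncc_threshold=detection.ncc_threshold,
        min_separation_um=detection.nms_factor * layout.pitch_um,
    )
    n_sample = min(detection.n_sample, detections.n_wells)
    detections = sample_wells(detections, n_sample, rng_seed=derive_seed(seed, "wells"))

    s = images.pixel_scale_um_per_px
    nuc_all = detect_nuclei(images.nuclei_all, s, nuclei_params, channel="all")
    nuc_dead = detect_nuclei(images.nuclei_dead, s, nuclei_params, channel="dead")

    asg_all = classify_location(
        assign_nearest_well(nuc_all, detections, use_sampled_only=True), layout
    )
    asg_dead = classify_location(
        assign_nearest_well(nuc_dead, detections, use_sampled_only=True), layout
    )

    in_set = asg_all[asg_all["in_sampled_set"].astype(bool)]
    n_total = len(in_set)
    n_interior = int((in_set["location"] == "interior").sum())
    try:
        eff = localization_efficiency(asg_all)
    except UndefinedStatisticError:
        eff = float("nan")
    dead_set = asg_dead[asg_dead["in_sampled_set"].astype(bool)]
    n_dead = int((dead_set["location"] == "interior").sum())
    try:
        viab = viability(asg_all, asg_dead, restrict_to_interior=True)
    except UndefinedStatisticError:
        viab = float("nan")
    occ_counts, single_pct = occupancy_distribution(asg_all, detections.sampled_ids)

    summary = PatterningSummary(
        condition=condition_name,
        n_wells_sampled=len(detections.sampled_ids),
        n_cells_total=n_total,
        n_cells_interior=n_interior,
        localization_efficiency_pct=eff,
        n_dead=n_dead,
        viability_pct=viab,
        occupancy_counts=occ_counts,
        single_cell_occupancy_pct=single_pct,
    )
    return SceneAnalysis(
        summary=summary,
        detections=detections,
        assignment_all=asg_all,
        assignment_dead=asg_dead,
    )


def run_scene(
    layout: ArrayLayout,
    condition: SeedingCondition,
    detection: DetectionConfig = DetectionConfig(),
    nuclei_params: NucleusParams = NucleusParams(),
    optics: Optics = Optics(),
    seed: int = 0,
    noise: bool = True,
) -> SceneAnalysis:
    """Simulate one scene and run the full analysis on it."""
    images, _ = simulate_scene(layout, condition, optics, seed=seed, noise=noise)
    return analyze_scene(
        images,
        layout,
        detection,
        nuclei_params,
        optics,
        seed=seed,
        condition_name=condition.name,
    )


# --------------------------------------------------------------------------
# file-based stages
# --------------------------------------------------------------------------

def _scene_dir(out_dir: Path, cond: ConditionConfig, rep: int) -> Path:
    arm = "stencil" if cond.stencil else "open"
    return out_dir / "scenes" / f"{cond.cell_line}_{cond.density_k_per_mL}K_{arm}_rep{rep}"


def _scene_seed(config: RunConfig, cond: ConditionConfig, rep: int) -> int:
    arm = "stencil" if cond.stencil else "open"
    return derive_seed(
        config.master_seed, cond.cell_line, arm, cond.density_k_per_mL, rep
    )


def run_simulate(config: RunConfig) -> list[Path]:
    """Write one scene directory per condition x replicate."""
    out = Path(config.out_dir)
    layout = config.layout.build()
    optics = config.optics.build()
    dirs = []
    for cond_cfg in config.conditions:
        for rep in range(1, config.replicates + 1):
            seed = _scene_seed(config, cond_cfg, rep)
            condition = cond_cfg.build(seed=seed)
            images, gt = simulate_scene(
                layout, condition, optics, seed=seed, noise=config.optics.noise
            )
            d = _scene_dir(out, cond_cfg, rep)
            write_scene(images, gt, d)
            log.info("simulated %s: %d cells", d.name, gt.n_cells)
            dirs.append(d)
    return dirs


def analyze_scene_dir(
    scene_dir: str | Path,
    detection: DetectionConfig = DetectionConfig(),
    nuclei_cfg: NucleiConfig = NucleiConfig(),
    optics: Optics = Optics(),
    seed: int = 0,
) -> SceneAnalysis:
    """Run the analysis stages on a scene directory from disk."""
    images, gt = read_scene(scene_dir)
    analysis = analyze_scene(
        images,
        gt.layout,
        detection,
        nuclei_cfg.build(),
        optics,
        seed=seed,
        condition_name=gt.condition.name,
    )
    d = Path(scene_dir)
    analysis.detections.to_frame().to_csv(d / "wells.csv", index=False)
    analysis.assignment_all.to_csv(d / "assignment_all.csv", index=False)
    analysis.assignment_dead.to_csv(d / "assignment_dead.csv", index=False)
    return analysis


def _summary_row(cond_cfg: ConditionConfig, rep: int, s: PatterningSummary) -> dict:
    row = {
        "cell_line": cond_cfg.cell_line,
        "density_k_per_mL": cond_cfg.density_k_per_mL,
        "stencil": cond_cfg.stencil,
        "replicate": rep,
        "condition": s.condition,
        "n_wells_sampled": s.n_wells_sampled,
        "n_cells_total": s.n_cells_total,
        "n_cells_interior": s.n_cells_interior,
        "localization_efficiency_pct": s.localization_efficiency_pct,
        "n_dead": s.n_dead,
        "viability_pct": s.viability_pct,
        "single_cell_occupancy_pct": s.single_cell_occupancy_pct,
    }
    for k, v in s.occupancy_counts.items():
        row[f"occ_{k}"] = v
    return row


def run_full(config: RunConfig) -> dict:
    """Execute every stage; returns paths of the emitted artifacts.

    Emits ``summary.csv`` (one row per condition x replicate),
    ``comparisons.csv`` (paired stencil vs. open tests per cell line x
    density) and ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = config.layout.build()
    optics = config.optics.build()
    nuc_params = config.nuclei.build()

    rows = []
    for cond_cfg in config.conditions:
        for rep in range(1, config.replicates + 1):
            seed = _scene_seed(config, cond_cfg, rep)
            condition = cond_cfg.build(seed=seed)
            name = f"{condition.name}-rep{rep}"
            if condition.no_data:
                log.info("skipping %s: no analysable data", name)
                rows.append(
                    {
                        "cell_line": cond_cfg.cell_line,
                        "density_k_per_mL": cond_cfg.density_k_per_mL,
                        "stencil": cond_cfg.stencil,
                        "replicate": rep,
                        "condition": condition.name,
                        "no_data": True,
                    }
                )
                continue
            analysis = run_scene(
                layout,
                condition,
                config.detection,
                nuc_params,
                optics,
                seed=seed,
                noise=config.optics.noise,
            )
            row = _summary_row(cond_cfg, rep, analysis.summary)
            row["no_data"] = False
            rows.append(row)
            log.info(
                "%s: eff=%.1f%% viab=%.1f%% single=%.1f%%",
                name,
                analysis.summary.localization_efficiency_pct,
                analysis.summary.viability_pct,
                analysis.summary.single_cell_occupancy_pct,
            )

    summary = pd.DataFrame(rows)
    summary_path = out / "summary.csv"
    summary.to_csv(summary_path, index=False)

    comparisons = _paired_comparisons(summary)
    comp_path = out / "comparisons.csv"
    comparisons.to_csv(comp_path, index=False)

    manifest_path = out / "manifest.json"
    files = sorted(
        str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        and p.name != "manifest.json"
    )
    manifest = {
        "software": f"wellpat {__version__}",
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "config": config.model_dump(mode="json"),
        "files": files + ["manifest.json"],
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "summary": summary_path,
        "comparisons": comp_path,
        "manifest": manifest_path,
        "summary_frame": summary,
        "comparisons_frame": comparisons,
    }


def _paired_comparisons(summary: pd.DataFrame) -> pd.DataFrame:
    """Stencil vs. open-substrate tests on per-replicate efficiencies."""
    rows = []
    if "no_data" in summary.columns:
        usable = summary[~summary["no_data"].astype(bool)]
    else:
        usable = summary
    for (line, dens), grp in usable.groupby(["cell_line", "density_k_per_mL"]):
        st = grp[grp["stencil"]]["localization_efficiency_pct"].dropna().to_numpy()
        op = grp[~grp["stencil"]]["localization_efficiency_pct"].dropna().to_numpy()
        if len(st) < 2 or len(op) < 2:
            continue
        t = students_t(st, op)
        u = mann_whitney_u(st, op)
        rows.append(
            {
                "cell_line": line,
                "density_k_per_mL": dens,
                "n_stencil": len(st),
                "n_open": len(op),
                "mean_eff_stencil": st.mean(),
                "mean_eff_open": op.mean(),
                "t_statistic": t.statistic,
                "t_p_value": t.p_value,
                "u_statistic": u.statistic,
                "u_p_value": u.p_value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_line",
            "density_k_per_mL",
            "n_stencil",
            "n_open",
            "mean_eff_stencil",
            "mean_eff_open",
            "t_statistic",
            "t_p_value",
            "u_statistic",
            "u_p_value",
        ],
    )
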