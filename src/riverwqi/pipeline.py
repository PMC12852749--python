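"""End-to-end assessment pipeline with a machine-readable run manifest.

One call chains the whole workflow: obtain a dataset (load a sample
table or simulate a scenario), compute both water-quality indices per
group, interpolate every (parameter, season) surface plus both index
surfaces, cross-validate the interpolation, correlate parameters with
the indices, and emit a plain-text report.  All outputs are delimited
text or Esri ASCII grids; exported tables are formatted to 4 decimals
for byte-stable regression comparison, with a full-precision sidecar.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .core import (
    Dataset,
    StandardsRegistry,
    load_samples,
    load_standards,
    read_mask_polygon,
    write_samples,
    write_sites_geo,
)
from .idw import IdwConfig, interpolate_grid, project_coords, write_raster
from .indices import compute_indices
from .synthetic import preset_scenario, scenario_from_file, simulate_dataset
from .validation import pearson_matrix, validation_report, validation_table

log = logging.getLogger("riverwqi.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunManifest:
    """Record of one pipeline run: inputs, settings, produced outputs."""

    config: dict
    config_digest: str
    tool_version: str
    steps: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)
    complete: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "tool_version": self.tool_version,
                "config": self.config,
                "config_digest": self.config_digest,
                "steps": self.steps,
                "outputs": self.outputs,
                "complete": self.complete,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunManifest":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            config=doc["config"],
            config_digest=doc["config_digest"],
            tool_version=doc["tool_version"],
            steps=doc["steps"],
            outputs=doc["outputs"],
            complete=doc["complete"],
        )


DEFAULT_CONFIG = {
    "scenario": None,  # preset name or scenario YAML path
    "samples": None,  # CSV sample table (alternative to scenario)
    "standards": None,  # standards YAML (None -> shipped default)
    "mask": None,  # optional corridor polygon (GeoJSON)
    "seed": 0,
    "power": 2.0,
    "cell_size": 100.0,
    "pool_seasons": False,
    "include_nonstatutory": False,
    "raster_parameters": None,  # None -> all parameters in the dataset
    "make_plots": False,
}


def _digest(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _resolve_dataset(config: dict, registry: StandardsRegistry) -> Dataset:
    if config.get("samples"):
        return load_samples(config["samples"], registry)
    name = config.get("scenario")
    if not name:
        raise PipelineError("input: config must set either 'scenario' or 'samples'")
    scenario = (
        scenario_from_file(name) if str(name).endswith(".yaml") else preset_scenario(name)
    )
    return simulate_dataset(scenario, seed=config.get("seed"))


def run_assessment(config: dict, outdir: str | Path) -> RunManifest:
    """Run the full assessment; return (and write) the run manifest.

    Any stage failure raises :class:`PipelineError` naming the stage;
    the partially filled manifest is still written with
    ``complete: false``.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=cfg, config_digest=_digest(cfg), tool_version=__version__
    )
    _setup_logging(outdir / "run.log")
    t0 = time.time()
    try:
        _run_stages(cfg, outdir, manifest)
        manifest.complete = True
    finally:
        manifest.steps.append({"stage": "total", "seconds": round(time.time() - t0, 3)})
        mpath = outdir / "manifest.json"
        mpath.write_text(manifest.to_json() + "\n", encoding="utf-8")
        manifest.outputs["manifest"] = str(mpath)
    return manifest


def _stage(manifest: RunManifest, name: str):
    log.info("stage %s", name)
    manifest.steps.append({"stage": name})


def _run_stages(cfg: dict, outdir: Path, manifest: RunManifest) -> None:
    # --- standards
    _stage(manifest, "standards")
    try:
        registry = load_standards(cfg.get("standards"))
    except Exception as exc:
        raise PipelineError(f"standards: {exc}") from exc

    # --- dataset
    _stage(manifest, "dataset")
    try:
        dataset = _resolve_dataset(cfg, registry)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"dataset: {exc}") from exc
    samples_path = outdir / "samples.csv"
    write_samples(dataset, samples_path, registry=registry)
    sites_path = outdir / "sites.geojson"
    write_sites_geo(dataset.sites, sites_path)
    manifest.outputs["samples"] = str(samples_path)
    manifest.outputs["sites"] = str(sites_path)

    # --- indices
    _stage(manifest, "indices")
    try:
        idx = compute_indices(
            dataset,
            registry,
            pool_seasons=cfg["pool_seasons"],
            include_nonstatutory=cfg["include_nonstatutory"],
        )
    except Exception as exc:
        raise PipelineError(f"indices: {exc}") from exc
    idx_path = outdir / "indices.csv"
    idx.to_csv(idx_path, index=False, float_format="%.4f")
    idx.to_csv(outdir / "indices_full.csv", index=False)
    manifest.outputs["indices"] = str(idx_path)

    # --- interpolation
    _stage(manifest, "interpolate")
    idw_cfg = IdwConfig(power=float(cfg["power"]))
    mask = read_mask_polygon(cfg["mask"]) if cfg.get("mask") else None
    raster_dir = outdir / "rasters"
    raster_dir.mkdir(exist_ok=True)
    try:
        frame = dataset.to_frame()
        lon0, lat0 = frame["longitude"].mean(), frame["latitude"].mean()
        x, y = project_coords(
            frame["longitude"].to_numpy(), frame["latitude"].to_numpy(),
            origin=(lon0, lat0),
        )
        frame = frame.assign(x=x, y=y)
        params = cfg.get("raster_parameters") or sorted(frame["parameter"].unique())
        n_rasters = 0
        for season, season_sub in frame.groupby("season"):
            for parameter in params:
                sub = season_sub[season_sub["parameter"] == parameter]
                if sub.empty:
                    continue
                pts = sub.groupby(["x", "y"], sort=True)["value"].mean().reset_index()
                surface = interpolate_grid(
                    pts[["x", "y"]].to_numpy(),
                    pts["value"].to_numpy(),
                    idw_cfg,
                    cell_size=float(cfg["cell_size"]),
                    mask=mask,
                    parameter=parameter,
                    season=str(season),
                )
                safe = parameter.replace("/", "_")
                write_raster(surface, raster_dir / f"{safe}_{season}.asc")
                n_rasters += 1
        # index surfaces per season ("represented geographically")
        if not cfg["pool_seasons"]:
            coord = (
                frame.groupby(["site_id", "sector"], sort=True)[["x", "y"]]
                .mean()
                .reset_index()
            )
            for season, season_idx in idx.groupby("season"):
                merged = season_idx.merge(coord, on=["site_id", "sector"])
                for col in ("wawqi", "cwqi"):
                    surface = interpolate_grid(
                        merged[["x", "y"]].to_numpy(),
                        merged[col].to_numpy(),
                        idw_cfg,
                        cell_size=float(cfg["cell_size"]),
                        mask=mask,
                        parameter=col.upper(),
                        season=str(season),
                    )
                    write_raster(surface, raster_dir / f"{col.upper()}_{season}.asc")
                    n_rasters += 1
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"interpolate: {exc}") from exc
    manifest.outputs["rasters"] = str(raster_dir)
    manifest.steps[-1]["n_rasters"] = n_rasters

    # --- validation
    _stage(manifest, "validate")
    try:
        loocv = validation_report(dataset, registry, idw_cfg)
    except Exception as exc:
        raise PipelineError(f"validate: {exc}") from exc
    val_path = outdir / "validation.csv"
    validation_table(loocv).to_csv(val_path, index=False, float_format="%.4f")
    manifest.outputs["validation"] = str(val_path)

    # --- correlation
    _stage(manifest, "correlate")
    try:
        corr = pearson_matrix(dataset, registry, pool_seasons=cfg["pool_seasons"])
    except Exception as exc:
        raise PipelineError(f"correlate: {exc}") from exc
    r_path = outdir / "correlation_r.csv"
    corr.to_frame().to_csv(r_path, float_format="%.4f")
    corr.p_frame().to_csv(outdir / "correlation_p.csv", float_format="%.4g")
    manifest.outputs["correlation_r"] = str(r_path)
    manifest.outputs["correlation_p"] = str(outdir / "correlation_p.csv")

    # --- report
    _stage(manifest, "report")
    report_path = outdir / "report.txt"
    _write_report(report_path, idx, loocv)
    manifest.outputs["report"] = str(report_path)
    if cfg.get("make_plots"):
        _plot_rasters(raster_dir, outdir / "maps")
        manifest.outputs["maps"] = str(outdir / "maps")


def _write_report(path: Path, idx, loocv) -> None:
    lines = ["Water-quality assessment summary", "=" * 34, ""]
    lines.append("Per-group index categories")
    lines.append("-" * 26)
    for _, row in idx.iterrows():
        lines.append(
            f"{row['site_id']:>4s} {row['sector']:<5s} {row['season']:<7s} "
            f"WAWQI {row['wawqi']:8.2f} ({row['wawqi_category']:<10s}) "
            f"CWQI {row['cwqi']:6.2f} ({row['cwqi_category']})"
        )
    flagged = idx[idx["wawqi"] > 50]
    lines.append("")
    lines.append(f"Hotspot flags (WAWQI poor or worse): {len(flagged)}")
    for _, row in flagged.iterrows():
        lines.append(
            f"  FLAG {row['site_id']}/{row['sector']}/{row['season']}: "
            f"WAWQI {row['wawqi']:.1f}, CWQI {row['cwqi']:.1f}"
        )
    lines.append("")
    lines.append("LOOCV of the interpolated surfaces")
    lines.append("-" * 34)
    lines.append(f"{'parameter':<14s}{'season':<8s}{'RMSE':>10s}{'MAE':>10s}  unit")
    for r in loocv:
        lines.append(
            f"{r.parameter:<14s}{r.season:<8s}{r.rmse:>10.4f}{r.mae:>10.4f}  {r.unit}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _plot_rasters(raster_dir: Path, map_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .idw import read_raster

    map_dir.mkdir(exist_ok=True)
    for asc in sorted(raster_dir.glob("*.asc")):
        surface = read_raster(asc)
        fig, ax = plt.subplots(figsize=(4, 8))
        im = ax.imshow(surface.values, aspect="auto", cmap="viridis")
        fig.colorbar(im, ax=ax, shrink=0.6)
        ax.set_title(asc.stem)
        fig.savefig(map_dir / f"{asc.stem}.png", dpi=80)
        plt.close(fig)


def render_report(manifest: RunManifest | str | Path) -> str:
    """Human-readable summary text for a completed run manifest."""
    if not isinstance(manifest, RunManifest):
        manifest = RunManifest.from_file(manifest)
    if not manifest.complete or "report" not in manifest.outputs:
        raise PipelineError("report: manifest is incomplete")
    return Path(manifest.outputs["report"]).read_text(encoding="utf-8")


def _setup_logging(logfile: Path) -> None:
    root = logging.getLogger("riverwqi")
    root.setLevel(logging.INFO)
    have_file = any(
        isinstance(h, logging.FileHandler)
        and getattr(h, "baseFilename", None) == str(logfile)
        for h in root.handlers
    )
    if not have_file:
        fh = logging.FileHandler(logfile, mode="a")
        fh.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        )
        root.addHandler(fh)
    if not any(
        isinstance(h, logging.StreamHandler) and h.stream is sys.stderr
        for h in root.handlers
    ):
        sh = logging.StreamHandler(sys.stderr)
        sh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        root.addHandler(sh)
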