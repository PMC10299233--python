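"""Pipeline orchestration: a single config drives any subset of the
pores / orientation / mechanics / stats / ramp stages, writes all outputs
under one directory and records a machine-readable manifest sufficient to
re-execute the identical run.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, mechanics, orientation, pores, ramp as rampmod
from .stats import FactorialDataset, anova_factorial, tukey_kramer
from .synthetic import RampSpec

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage tag."""


@dataclass
class PipelineConfig:
    out_dir: str = "scaffoldquant_run"
    seed: int = 0
    # pores stage
    pore_images: list = dc_field(default_factory=list)
    pixel_scale: float = 1.0
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    polarity: str = "dark_pores"
    connectivity: int = 8
    min_area_px: int = 5
    # orientation stage
    orient_images: list = dc_field(default_factory=list)
    roi: list | None = None
    window_sigma: float = 2.0
    bin_width_deg: float = 1.0
    # mechanics stage
    traction_logs: list = dc_field(default_factory=list)
    gauge_length_mm: float = 35.0
    diameter_mm: float = 5.0
    pretension_g: float = 3.0
    failure_fraction: float = 0.30
    # stats stage
    stats_table: str | None = None
    response: str | None = None
    factors: list = dc_field(default_factory=list)
    posthoc_factor: str | None = None
    # ramp stage
    ramp_log: str | None = None
    ramp_nominal: dict = dc_field(default_factory=dict)
    ramp_tolerance_C: float = 1.0

    def input_paths(self) -> list[str]:
        paths = [*self.pore_images, *self.orient_images, *self.traction_logs]
        if self.stats_table:
            paths.append(self.stats_table)
        if self.ramp_log:
            paths.append(self.ramp_log)
        return paths


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML (or JSON; YAML is a superset) config file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _stage_pores(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    tables = []
    for p in cfg.pore_images:
        img = io.read_image(p, pixel_scale=cfg.pixel_scale)
        res = pores.analyze_image(
            img, method=cfg.threshold_method,
            fixed_threshold=cfg.fixed_threshold, polarity=cfg.polarity,
            connectivity=cfg.connectivity, min_area_px=cfg.min_area_px)
        tab = res["table"].copy()
        tab.insert(0, "image", Path(p).name)
        tables.append(tab)
        manifest["stages"]["pores"]["images"].append(
            {"path": str(p), "pore_count": res["pore_count"],
             "dropped_small": res["dropped_small"],
             "threshold_used": res["threshold_used"]})
    all_tab = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    io.write_pore_table(out / "pores.csv", all_tab)


def _stage_orient(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    for p in cfg.orient_images:
        img = io.read_image(p, pixel_scale=cfg.pixel_scale)
        roi = tuple(cfg.roi) if cfg.roi else None
        hist = orientation.analyze_image(
            img, roi=roi, window_sigma=cfg.window_sigma,
            bin_width_deg=cfg.bin_width_deg)
        io.write_histogram_csv(out / f"orientation_{Path(p).stem}.csv", hist)
        manifest["stages"]["orient"]["images"].append(
            {"path": str(p), "peak_angle_deg": hist.peak_angle_deg,
             "peak_density": hist.peak_density,
             "mean_coherency": hist.meta["mean_coherency"]})


def _stage_mech(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    rows = []
    for p in cfg.traction_logs:
        df = io.read_traction_csv(p)
        log = mechanics.TractionLog.from_frame(
            df, gauge_length_mm=cfg.gauge_length_mm,
            diameter_mm=cfg.diameter_mm, labels={"source": Path(p).name})
        curve, summary = mechanics.analyze_log(
            log, pretension_g=cfg.pretension_g,
            failure_fraction=cfg.failure_fraction)
        io.write_curve_csv(out / f"curve_{Path(p).stem}.csv", curve)
        rows.append({"log": Path(p).name,
                     "modulus_kPa": summary.modulus_kPa,
                     "uts_kPa": summary.uts_kPa,
                     "elongation_break_pct": summary.elongation_break_pct,
                     "fit_r2": summary.fit_r2,
                     "flags": ";".join(summary.flags)})
    pd.DataFrame(rows).to_csv(out / "mechanics_summary.csv", index=False,
                              lineterminator="\n")
    manifest["stages"]["mech"]["specimens"] = rows


def _stage_stats(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    df = pd.read_csv(cfg.stats_table)
    ds = FactorialDataset(df, response=cfg.response, factors=list(cfg.factors))
    results = anova_factorial(ds)
    pd.DataFrame(
        [{"term": r.term, "F": r.statistic, "p_value": r.p_value, "df": r.df}
         for r in results]
    ).to_csv(out / "anova.csv", index=False, lineterminator="\n")
    if cfg.posthoc_factor:
        tk = tukey_kramer(ds, cfg.posthoc_factor)
        tk.to_csv(out / "tukey.csv", index=False, lineterminator="\n")
    manifest["stages"]["stats"]["terms"] = [
        {"term": r.term, "F": r.statistic, "p": r.p_value} for r in results]


def _stage_ramp(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    log = io.read_ramp_csv(cfg.ramp_log)
    nominal = RampSpec(**cfg.ramp_nominal) if cfg.ramp_nominal else RampSpec()
    report = rampmod.verify_ramp(log, nominal, tolerance_C=cfg.ramp_tolerance_C)
    io.write_json(out / "ramp_report.json", asdict(report))
    manifest["stages"]["ramp"]["report"] = asdict(report)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest.

    Pre-flight checks every referenced input path before any stage runs;
    a stage failure aborts with a stage-tagged diagnostic and flags the
    partial outputs in the manifest.
    """
    missing = [p for p in cfg.input_paths() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input paths: {missing}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": {"name": "scaffoldquant", "version": __version__},
        "seed": cfg.seed,
        "config": {k: v for k, v in asdict(cfg).items()},
        "stages": {},
        "complete": False,
    }
    stages = [
        ("pores", bool(cfg.pore_images), _stage_pores, {"images": []}),
        ("orient", bool(cfg.orient_images), _stage_orient, {"images": []}),
        ("mech", bool(cfg.traction_logs), _stage_mech, {}),
        ("stats", bool(cfg.stats_table), _stage_stats, {}),
        ("ramp", bool(cfg.ramp_log), _stage_ramp, {}),
    ]
    np.random.seed(cfg.seed % (2**31))  # stages are deterministic; belt & braces
    for name, enabled, fn, init in stages:
        if not enabled:
            continue
        manifest["stages"][name] = init
        try:
            fn(cfg, out, manifest)
        except Exception as exc:
            manifest["stages"][name]["error"] = str(exc)
            io.write_json(out / "manifest.json", manifest)
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    manifest["complete"] = True
    io.write_json(out / "manifest.json", manifest)
    return manifest
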