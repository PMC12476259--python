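"""End-to-end orchestration: preprocess -> OSH -> peaks -> segmentation ->
classification -> evaluation, driven by a validated configuration and leaving
a reproducible run manifest.

The pipeline operates on a dataset manifest (CSV of image/mask/label paths).
Per image it computes the phase-current amplitude map on the shared reference
scale, the global peak (cell centre C and amplitude A_max), the automatic
initial contour, and the Chan-Vese mask; stage outputs are CSV/PNG/JSON files
under the output directory. All randomness derives from the single config
seed; two runs with the same config produce byte-identical artifacts.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .classify import (AmplitudeRecord, ClassIntervals, classify_amplitude,
                       default_intervals, fit_intervals)
from .contours import ContourParams, evolve_chan_vese
from .errors import ConfigError, DataError, HolosegError
from .imaging import (DatasetManifest, RasterImage, preprocess, read_image,
                      read_mask, write_mask)
from .metrics import accuracy_and_loss, aggregate_seg_metrics, seg_metrics
from .osh import OSHParams, phase_current_map, reference_gain
from .peaks import (DEFAULT_SMOOTH_SIGMA, find_global_peak,
                    initial_contour_from_peak)
from .phantom import PhantomSpec, generate_dataset

logger = logging.getLogger(__name__)

#: Full configuration schema with defaults; unknown keys are rejected.
DEFAULT_CONFIG: Dict[str, Dict] = {
    "seed": 0,
    "input": {"manifest": None},
    "output": {"dir": "holoseg_out"},
    "simulate": {"n_per_class": 10, "noise_sigma": 0.01, "side": 224},
    "preprocess": {"side": 224, "channel": "V", "invert": True},
    "osh": {"radius_frac": 0.15, "mode": "fourier_ppf", "scale": "reference",
            "amplitude_sigma": 2.0, "background_ref": None},
    "detect": {"smooth_sigma": DEFAULT_SMOOTH_SIGMA, "policy": "halfmax_region",
               "r0": 10.0},
    "seg": {"enabled": True, "method": "chan_vese", "mu": 0.2, "dt": 0.5,
            "max_iter": 400, "tol": 1e-8, "on": "inverted_intensity",
            "opening_radius": 2, "keep_component": True},
    "classify": {"enabled": True, "policy": "strict", "intervals": "default",
                 "fit_method": "minmax", "fit_q": 0.0},
    "evaluate": {"enabled": True},
}


def _merge_validate(defaults: Dict, override: Dict, path: str = "") -> Dict:
    out = copy.deepcopy(defaults)
    for key, val in (override or {}).items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {where}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"configuration key {where} must be a mapping")
            out[key] = _merge_validate(defaults[key], val, where)
        else:
            out[key] = val
    return out


@dataclass
class PipelineConfig:
    """Validated configuration with every default materialised."""

    settings: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.settings = _merge_validate(DEFAULT_CONFIG, self.settings)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(settings=data)

    def __getitem__(self, key):
        return self.settings[key]


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, artifact hashes, timings."""

    config: Dict
    version: str = _pkg_version
    started: str = ""
    finished: str = ""
    status: str = "running"
    stages: List[str] = field(default_factory=list)
    artifact_hashes: Dict[str, str] = field(default_factory=dict)
    error: Optional[str] = None

    def write(self, out_dir) -> None:
        path = os.path.join(out_dir, "run_manifest.json")
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _contour_params(seg_cfg: Dict) -> ContourParams:
    return ContourParams(mu=seg_cfg["mu"], dt=seg_cfg["dt"],
                         max_iter=seg_cfg["max_iter"], tol=seg_cfg["tol"])


def process_image(img: RasterImage, cfg: PipelineConfig,
                  gain: Optional[float] = None) -> Dict:
    """Run one image through preprocess/OSH/peak/seed (no segmentation).

    Returns a dict with the preprocessed GRAY image, the phase-current map,
    the peak, and the initial contour.
    """
    pre = cfg["preprocess"]
    osh_cfg = cfg["osh"]
    det = cfg["detect"]
    gray = preprocess(img, side=pre["side"], channel=pre["channel"],
                      do_invert=pre["invert"])
    params = OSHParams(filter_radius_frac=osh_cfg["radius_frac"],
                       mode="fourier_ppf", scale=osh_cfg["scale"],
                       amplitude_sigma=osh_cfg["amplitude_sigma"])
    if osh_cfg["scale"] == "reference" and gain is None:
        gain = reference_gain(gray.shape, params.filter_radius_frac,
                              params.soft_edge, params.amplitude_sigma)
    pc_map = phase_current_map(gray, params, gain=gain)
    peak = find_global_peak(pc_map, smooth_sigma=det["smooth_sigma"])
    seed = initial_contour_from_peak(pc_map, peak, policy=det["policy"],
                                     r0=det["r0"],
                                     smooth_sigma=det["smooth_sigma"])
    return {"gray": gray, "map": pc_map, "peak": peak, "seed": seed,
            "a_max": float(pc_map.amplitude.max()), "gain": gain}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all enabled stages over the input manifest.

    Artifacts written under output.dir: amplitudes.csv, peaks.csv, masks/
    (PNG per image), predictions.csv, seg_metrics.csv, summary.json and
    run_manifest.json. The manifest is written on failure as well.
    """
    cfg = config
    out_dir = cfg["output"]["dir"]
    os.makedirs(out_dir, exist_ok=True)
    manifest = RunManifest(config=copy.deepcopy(cfg.settings),
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    try:
        result = _run_stages(cfg, out_dir, manifest)
        manifest.status = "success"
        return result
    except HolosegError as exc:
        manifest.status = "failed"
        manifest.error = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.write(out_dir)


def _run_stages(cfg: PipelineConfig, out_dir: str,
                manifest: RunManifest) -> RunManifest:
    man_path = cfg["input"]["manifest"]
    if not man_path:
        raise ConfigError("input.manifest is required (CSV of image paths)")
    dataset = DatasetManifest.read_csv(man_path)
    if len(dataset) == 0:
        raise DataError(f"empty manifest: {man_path}")

    seg_cfg = cfg["seg"]
    do_seg = bool(seg_cfg["enabled"])
    masks_dir = os.path.join(out_dir, "masks")
    if do_seg:
        os.makedirs(masks_dir, exist_ok=True)

    rows = []
    seg_rows = []
    per_image_metrics = []
    gain = None
    cparams = _contour_params(seg_cfg)
    for idx, rec in dataset.records.iterrows():
        img = read_image(rec["image_path"])
        stage = process_image(img, cfg, gain=gain)
        gain = stage["gain"]
        peak = stage["peak"]
        rows.append({
            "image_path": rec["image_path"], "row": peak.center[0],
            "col": peak.center[1], "amplitude": peak.amplitude,
            "a_max": stage["a_max"], "label": rec.get("label") or "",
        })
        if do_seg:
            seg_input = (stage["gray"] if seg_cfg["on"] == "inverted_intensity"
                         else RasterImage(stage["map"].amplitude / 255.0, "GRAY"))
            result = evolve_chan_vese(
                seg_input, stage["seed"], cparams,
                keep_component=seg_cfg["keep_component"],
                opening_radius=seg_cfg["opening_radius"], full_output=True)
            mask_path = os.path.join(masks_dir, f"mask_{idx:05d}.png")
            write_mask(result.mask, mask_path)
            seg_rows.append({"image_path": rec["image_path"],
                             "mask_path": mask_path,
                             "iterations": result.iterations,
                             "final_energy": result.energy_history[-1]})
            if rec.get("mask_path"):
                truth = read_mask(rec["mask_path"])
                per_image_metrics.append(seg_metrics(result.mask, truth))
    manifest.stages.append("phase+detect")

    amp_path = os.path.join(out_dir, "amplitudes.csv")
    pd.DataFrame(rows).to_csv(amp_path, index=False)
    manifest.artifact_hashes["amplitudes.csv"] = _sha256(amp_path)
    if do_seg:
        seg_path = os.path.join(out_dir, "segmentation.csv")
        pd.DataFrame(seg_rows).to_csv(seg_path, index=False)
        manifest.artifact_hashes["segmentation.csv"] = _sha256(seg_path)
        manifest.stages.append("segment")

    summary: Dict = {}
    cls_cfg = cfg["classify"]
    if cls_cfg["enabled"]:
        records = [AmplitudeRecord(image_id=r["image_path"], a_max=r["a_max"],
                                   true_label=(r["label"] or None))
                   for r in rows]
        if cls_cfg["intervals"] == "fit":
            labelled = [r for r in records if r.true_label]
            intervals = fit_intervals(labelled, method=cls_cfg["fit_method"],
                                      q=cls_cfg["fit_q"])
        elif cls_cfg["intervals"] == "default":
            intervals = default_intervals()
        else:
            intervals = ClassIntervals.from_yaml(cls_cfg["intervals"])
        intervals.to_yaml(os.path.join(out_dir, "intervals.yaml"))
        preds = [{"image_id": r.image_id, "a_max": r.a_max,
                  "predicted": classify_amplitude(r.a_max, intervals,
                                                  policy=cls_cfg["policy"]),
                  "true": r.true_label or ""} for r in records]
        pred_path = os.path.join(out_dir, "predictions.csv")
        pd.DataFrame(preds).to_csv(pred_path, index=False)
        manifest.artifact_hashes["predictions.csv"] = _sha256(pred_path)
        manifest.stages.append("classify")

        if cfg["evaluate"]["enabled"]:
            truthy = [(p["predicted"], p["true"]) for p in preds if p["true"]]
            if truthy:
                report = accuracy_and_loss([p for p, _ in truthy],
                                           [t for _, t in truthy])
                summary["classification"] = {
                    "accuracy_pct": report.accuracy_pct,
                    "loss_pct": report.loss_pct,
                    "n": len(truthy),
                }

    if cfg["evaluate"]["enabled"] and per_image_metrics:
        summary["segmentation"] = aggregate_seg_metrics(per_image_metrics)
        summary["segmentation"]["n"] = len(per_image_metrics)
    if summary:
        sum_path = os.path.join(out_dir, "summary.json")
        with open(sum_path, "w") as fh:
            json.dump(summary, fh, indent=2)
        manifest.artifact_hashes["summary.json"] = _sha256(sum_path)
        manifest.stages.append("evaluate")
    return manifest


def simulate_dataset(cfg: PipelineConfig, out_dir: Optional[str] = None):
    """Generate the synthetic dataset described by the simulate section."""
    sim = cfg["simulate"]
    spec = PhantomSpec(n_per_class=sim["n_per_class"], side=sim["side"],
                       noise_sigma=sim["noise_sigma"], seed=cfg["seed"])
    target = out_dir or os.path.join(cfg["output"]["dir"], "dataset")
    return generate_dataset(spec, target)
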