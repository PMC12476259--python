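"""Synthetic blood-smear phantoms with ground-truth masks and labels.

Each phantom emulates the salient structure of a stained smear micrograph:
a pink plasma background, a scatter of semi-transparent light-red red-blood-
cell discs, and one dominant dark-purple leukocyte (a randomly deformed
ellipse) whose darkness is class-dependent, so the four classes produce four
separated bands of maximum phase-current amplitude. The rasterised leukocyte
is the exact ground-truth mask. Phantoms are parametric shapes, not realistic
textures — enough to exercise every pipeline operator end to end.

All randomness flows from a single spec-level seed through
``numpy.random.SeedSequence`` child streams, one per image.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError
from .imaging import (CLASS_LABELS, BinaryMask, DatasetManifest, RasterImage,
                      write_image, write_mask)

#: Class-dependent mean leukocyte darkness (1 - V value of the blob) chosen by
#: bisection calibration so the reference-scaled maximum phase-current
#: amplitudes land in the four published bands (benign highest).
DEFAULT_CLASS_CONTRAST: Dict[str, float] = {
    "benign": 0.3800,
    "malignant-early": 0.2431,
    "malignant-pre": 0.1812,
    "malignant-pro": 0.0800,
}

_BACKGROUND_RGB = np.array([0.97, 0.80, 0.85])  # pink plasma
_RBC_RGB = np.array([0.95, 0.60, 0.65])  # light red erythrocytes
_WBC_CHROMA = np.array([0.85, 0.55, 1.00])  # purple: RGB = value * chroma


@dataclass
class PhantomSpec:
    """Study conditions of the synthetic dataset.

    class_contrast levels must stay pairwise separated by at least three
    noise standard deviations so the amplitude bands cannot merge by noise
    alone.
    """

    n_per_class: int = 100
    side: int = 224
    wbc_radius_range: Tuple[float, float] = (22.5, 23.5)
    class_contrast: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_CONTRAST))
    contrast_jitter: float = 0.003
    rbc_count_range: Tuple[int, int] = (25, 60)
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ParameterError("n_per_class must be >= 1")
        r_lo, r_hi = self.wbc_radius_range
        if not (0 < r_lo <= r_hi < self.side / 3):
            raise ParameterError("wbc radii must be positive and < side/3")
        levels = sorted(self.class_contrast.values())
        for a, b in zip(levels, levels[1:]):
            if b - a < 3.0 * self.noise_sigma:
                raise ParameterError(
                    "class contrasts must be separated by >= 3 * noise_sigma")

    def to_yaml(self, path) -> None:
        data = {
            "n_per_class": self.n_per_class, "side": self.side,
            "wbc_radius_range": list(self.wbc_radius_range),
            "class_contrast": {k: float(v) for k, v in self.class_contrast.items()},
            "contrast_jitter": self.contrast_jitter,
            "rbc_count_range": list(self.rbc_count_range),
            "noise_sigma": self.noise_sigma, "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


@dataclass
class PhantomSample:
    image: RasterImage
    mask: BinaryMask
    label: str
    provenance: Dict


def _deformed_ellipse_mask(side: int, center, radius: float, axis_ratio: float,
                           angle: float, harmonics, rng) -> np.ndarray:
    """Rasterise a radially perturbed ellipse: r(theta) = r * (1 + sum a_k cos(k theta + p_k))."""
    yy, xx = np.mgrid[:side, :side]
    dy = yy - center[0]
    dx = xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    rr = np.hypot(u / 1.0, v / axis_ratio)
    theta = np.arctan2(v / axis_ratio, u)
    bound = np.full_like(theta, radius)
    for k, (amp, ph) in enumerate(harmonics, start=2):
        bound = bound * (1.0 + amp * np.cos(k * theta + ph))
    return (rr <= bound).astype(np.uint8)


def generate_phantom(spec: PhantomSpec, label: str,
                     rng: np.random.Generator) -> PhantomSample:
    """Draw one phantom: RBC-textured pink background plus one leukocyte blob."""
    if label not in CLASS_LABELS:
        raise ParameterError(f"unknown class label {label!r}")
    if label not in spec.class_contrast:
        raise ParameterError(f"no contrast level configured for {label!r}")
    side = spec.side
    img = np.ones((side, side, 3)) * _BACKGROUND_RGB

    n_rbc = int(rng.integers(spec.rbc_count_range[0], spec.rbc_count_range[1] + 1))
    yy, xx = np.mgrid[:side, :side]
    for _ in range(n_rbc):
        r = rng.uniform(7.0, 13.0)
        cy = rng.uniform(0, side)
        cx = rng.uniform(0, side)
        alpha = rng.uniform(0.25, 0.55)
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        img[disk] = (1.0 - alpha) * img[disk] + alpha * _RBC_RGB

    radius = rng.uniform(*spec.wbc_radius_range)
    margin = radius * 1.35 + 6.0
    if 2 * margin >= side:
        raise ParameterError("leukocyte radius infeasible for this image side")
    placed = None
    for _ in range(100):
        cy = rng.uniform(margin, side - margin)
        cx = rng.uniform(margin, side - margin)
        placed = (cy, cx)
        break
    axis_ratio = rng.uniform(0.95, 1.0)
    angle = rng.uniform(0.0, np.pi)
    harmonics = [(rng.uniform(0.0, 0.02), rng.uniform(0.0, 2 * np.pi))
                 for _ in range(3)]
    mask = _deformed_ellipse_mask(side, placed, radius, axis_ratio, angle,
                                  harmonics, rng)
    if not mask.any():
        raise ParameterError("degenerate leukocyte rasterisation")

    darkness = float(np.clip(
        spec.class_contrast[label] + rng.normal(0.0, spec.contrast_jitter),
        0.02, 0.98))
    blob_value = 1.0 - darkness  # V channel inside the cell
    img[mask.astype(bool)] = blob_value * _WBC_CHROMA

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)

    provenance = {
        "label": label, "center": [float(placed[0]), float(placed[1])],
        "radius": float(radius), "darkness": darkness,
        "axis_ratio": float(axis_ratio), "n_rbc": n_rbc,
    }
    return PhantomSample(image=RasterImage(img, "RGB"), mask=BinaryMask(mask),
                         label=label, provenance=provenance)


def iter_samples(spec: PhantomSpec):
    """Deterministically yield (index, PhantomSample) over all classes.

    Child RNG streams are derived per image from the spec seed, so any prefix
    of the stream is reproducible independent of consumption order.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(len(CLASS_LABELS) * spec.n_per_class)
    i = 0
    for label in CLASS_LABELS:
        for _ in range(spec.n_per_class):
            rng = np.random.default_rng(children[i])
            yield i, generate_phantom(spec, label, rng)
            i += 1


def generate_dataset(spec: PhantomSpec, out_dir) -> DatasetManifest:
    """Write images, masks, a manifest CSV and the spec YAML under out_dir."""
    out_dir = os.fspath(out_dir)
    rows = []
    counters = {label: 0 for label in CLASS_LABELS}
    for _, sample in iter_samples(spec):
        label = sample.label
        counters[label] += 1
        cls_dir = os.path.join(out_dir, label)
        os.makedirs(cls_dir, exist_ok=True)
        img_path = os.path.join(cls_dir, f"img_{counters[label]:04d}.png")
        msk_path = os.path.join(cls_dir, f"msk_{counters[label]:04d}.png")
        write_image(sample.image, img_path)
        write_mask(sample.mask, msk_path)
        rows.append({"image_path": img_path, "mask_path": msk_path, "label": label})
    manifest = DatasetManifest(records=pd.DataFrame(rows))
    manifest.write_csv(os.path.join(out_dir, "manifest.csv"))
    spec.to_yaml(os.path.join(out_dir, "phantom_spec.yaml"))
    return manifest


def measure_amplitude(sample: PhantomSample, params=None,
                      gain: Optional[float] = None) -> float:
    """Reference-scaled maximum phase-current amplitude of one phantom."""
    from .imaging import preprocess
    from .osh import OSHParams, phase_current_map

    gray = preprocess(sample.image, side=sample.image.shape[0])
    if params is None:
        params = OSHParams(scale="reference")
    return float(phase_current_map(gray, params, gain=gain).amplitude.max())


def calibrate_contrast(target_amplitude: float, spec: PhantomSpec,
                       label: str = "benign", n_probe: int = 5,
                       lo: float = 0.02, hi: float = 0.98,
                       max_iter: int = 20, tol: float = 0.5) -> float:
    """Bisection on blob darkness against the measured mean amplitude.

    Exploits the empirical monotone increase of peak phase coherence with
    leukocyte contrast. Returns the darkness level whose mean amplitude over
    n_probe phantoms is within tol of target_amplitude (or the best bracket
    midpoint after max_iter).
    """
    from .osh import OSHParams, reference_gain

    params = OSHParams(scale="reference")
    gain = reference_gain((spec.side, spec.side), params.filter_radius_frac,
                          params.soft_edge, params.amplitude_sigma)

    def mean_amp(contrast: float) -> float:
        probe_spec = replace(spec, class_contrast={label: contrast},
                             contrast_jitter=0.0)
        ss = np.random.SeedSequence([probe_spec.seed, 917])
        vals = []
        for child in ss.spawn(n_probe):
            sample = generate_phantom(probe_spec, label, np.random.default_rng(child))
            vals.append(measure_amplitude(sample, params=params, gain=gain))
        return float(np.mean(vals))

    a_lo, a_hi = mean_amp(lo), mean_amp(hi)
    if not (min(a_lo, a_hi) - tol <= target_amplitude <= max(a_lo, a_hi) + tol):
        raise ParameterError(
            f"target amplitude {target_amplitude} outside attainable range "
            f"[{min(a_lo, a_hi):.1f}, {max(a_lo, a_hi):.1f}]")
    increasing = a_hi >= a_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        a_mid = mean_amp(mid)
        if abs(a_mid - target_amplitude) <= tol:
            return mid
        if (a_mid < target_amplitude) == increasing:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
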