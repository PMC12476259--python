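"""Phase-current peak detection and automatic initial-contour construction.

The global amplitude peak of the reconstructed phase current marks the
leukocyte: its location is the cell centre C, its height L the classification
amplitude, and the surrounding high-amplitude region seeds the active-contour
segmentation (the initial contour Ci), replacing manual initialisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from .errors import DegenerateInputError, ParameterError
from .imaging import BinaryMask
from .osh import PhaseCurrentMap

logger = logging.getLogger(__name__)

#: Gaussian sigma (pixels) used to stabilise peak localisation — roughly half
#: the nominal cell radius, so localisation acts like a matched filter at cell
#: scale. Classification amplitudes are always read from the unsmoothed map.
DEFAULT_SMOOTH_SIGMA = 10.0
DEFAULT_FALLBACK_RADIUS = 10.0  # px at 224x224, fixed-circle seed fallback


@dataclass
class PeakInfo:
    """Cell centre C and peak amplitude L on the 0-255 amplitude scale."""

    center: Tuple[int, int]
    amplitude: float


@dataclass
class InitialContour:
    """Seed region Ci for contour evolution, strictly inside the image."""

    seed_mask: BinaryMask
    center: Tuple[int, int]
    radius: Optional[float] = None  # set when the fixed-circle policy was used

    def __post_init__(self):
        if self.seed_mask.area() == 0:
            raise ParameterError("initial contour seed mask is empty")


def _check_map(pc_map: PhaseCurrentMap) -> np.ndarray:
    amp = pc_map.amplitude
    if not np.all(np.isfinite(amp)):
        raise ParameterError("amplitude map contains non-finite values")
    return amp


def find_global_peak(pc_map: PhaseCurrentMap, smooth_sigma: float = 0.0) -> PeakInfo:
    """Locate the global amplitude maximum; ties resolved to smallest (row, col).

    With smooth_sigma > 0 the location is taken from a Gaussian-smoothed copy
    (noise-robust localisation) while the amplitude is read from the raw map.
    """
    amp = _check_map(pc_map)
    if amp.max() - amp.min() < 1e-12:
        raise DegenerateInputError("constant amplitude map has no peak")
    work = ndimage.gaussian_filter(amp, smooth_sigma) if smooth_sigma > 0 else amp
    idx = np.unravel_index(int(np.argmax(work)), work.shape)  # row-major: lexicographic tie-break
    return PeakInfo(center=(int(idx[0]), int(idx[1])), amplitude=float(amp[idx]))


def find_cell_peaks(pc_map: PhaseCurrentMap, min_distance: int = 15,
                    rel_threshold: float = 0.5,
                    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA) -> List[PeakInfo]:
    """Local amplitude maxima above rel_threshold x global max, NMS-separated.

    Detection runs on a Gaussian-smoothed copy; reported amplitudes and the
    threshold comparison use the raw map. Sorted by descending amplitude,
    ties by (row, col).
    """
    if min_distance < 1:
        raise ParameterError("min_distance must be >= 1")
    if not (0.0 < rel_threshold <= 1.0):
        raise ParameterError("rel_threshold must lie in (0, 1]")
    amp = _check_map(pc_map)
    if amp.max() - amp.min() < 1e-12:
        return []
    work = ndimage.gaussian_filter(amp, smooth_sigma) if smooth_sigma > 0 else amp
    coords = peak_local_max(work, min_distance=int(min_distance), exclude_border=False)
    peaks = []
    cutoff = rel_threshold * amp.max() - 1e-12
    for r, c in coords:
        a = float(amp[r, c])
        if a >= cutoff:
            peaks.append(PeakInfo(center=(int(r), int(c)), amplitude=a))
    peaks.sort(key=lambda p: (-p.amplitude, p.center))
    return peaks


def _clear_border(mask: np.ndarray) -> np.ndarray:
    out = mask.copy()
    out[0, :] = out[-1, :] = 0
    out[:, 0] = out[:, -1] = 0
    return out


def _fixed_circle_mask(shape, center, r0: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    disk = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r0 ** 2
    return _clear_border(disk.astype(np.uint8))


def initial_contour_from_peak(pc_map: PhaseCurrentMap, peak: PeakInfo,
                              policy: str = "halfmax_region",
                              r0: float = DEFAULT_FALLBACK_RADIUS,
                              smooth_sigma: float = DEFAULT_SMOOTH_SIGMA) -> InitialContour:
    """Build the seed region Ci around a phase-current peak.

    halfmax_region: connected component containing the peak of the region
    above the half-maximum level (on the smoothed map), eroded by one pixel
    so the contour starts strictly inside the cell. The level is measured
    above the map's background floor (its median), level = bg + 0.5 (L - bg),
    which reduces to L/2 on clean zero-background maps and stays peak-local
    on speckled ones. Falls back to a fixed circle of radius r0 when the
    eroded region vanishes. fixed_circle: disk of radius r0 at the peak,
    clipped one pixel inside the borders.
    """
    amp = _check_map(pc_map)
    h, w = amp.shape
    r, c = peak.center
    if not (0 <= r < h and 0 <= c < w):
        raise ParameterError(f"peak centre {peak.center} outside map {amp.shape}")
    if policy not in ("halfmax_region", "fixed_circle"):
        raise ParameterError(f"unknown seed policy {policy!r}")

    if policy == "halfmax_region":
        work = ndimage.gaussian_filter(amp, smooth_sigma) if smooth_sigma > 0 else amp
        bg = float(np.median(work))
        level = bg + 0.5 * (work[r, c] - bg)
        region = work >= level
        labels, _ = ndimage.label(region)
        comp = labels == labels[r, c]
        comp = ndimage.binary_erosion(comp, border_value=0)
        comp = _clear_border(comp.astype(np.uint8))
        if comp.any() and comp[r, c]:
            return InitialContour(seed_mask=BinaryMask(comp), center=(r, c))
        logger.warning("halfmax seed region empty after erosion at %s; "
                       "falling back to fixed circle r0=%s", peak.center, r0)

    disk = _fixed_circle_mask(amp.shape, (r, c), r0)
    if not disk.any():  # centre hugging a border of a tiny image
        rr = int(np.clip(r, 1, h - 2))
        cc = int(np.clip(c, 1, w - 2))
        disk = np.zeros_like(amp, dtype=np.uint8)
        disk[rr, cc] = 1
    return InitialContour(seed_mask=BinaryMask(disk), center=(r, c), radius=float(r0))
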