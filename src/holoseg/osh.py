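"""Digital simulation of optical scanning holography (OSH).

The optical record-and-reconstruct cycle is modelled in the Fourier domain:
the input plane is transformed to its centred spectrum, a pure phase filter
(PPF) whitens the spectrum to unit modulus, a circular high-pass window
removes low-frequency illumination structure, and an inverse transform
reconstructs a complex field — the simulated "phase current". The modulus of
that field, mapped onto a 0-255 scale, is the amplitude map whose global peak
localises the leukocyte and whose height drives classification.

Two amplitude scales are provided:

``minmax255``
    per-image min-max stretch; every image's maximum becomes 255. Good for
    visualisation and peak localisation, blind to inter-image contrast.
``reference``
    a fixed gain calibrated on a white-disc calibration image of nominal cell
    size (a perfectly opaque, perfectly coherent cell), whose peak defines
    255. The gain is shared by all images of one geometry, so inter-image
    amplitude ordering is preserved. This scale is the one used for
    classification.

An optional Fresnel-zone-plate (FZP) mode builds the sine/cosine holograms of
scanning holography by convolving the object intensity with the chirp kernels
(k0 / 2 pi z) sin|cos(k0 r^2 / 2 z).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .errors import ParameterError
from .imaging import RasterImage

AMPLITUDE_MAX = 255.0

#: stated admissible band for the circular stop-band radius (fraction of Nyquist)
RADIUS_FRAC_BAND = (0.10, 0.20)
DEFAULT_RADIUS_FRAC = 0.15  # midpoint of the admissible band


@dataclass
class Spectrum:
    """Centred 2-D spectrum: zero frequency at the array centre."""

    values: np.ndarray
    grid: tuple

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ParameterError("spectrum must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("spectrum contains non-finite values")
        self.grid = tuple(self.values.shape)


@dataclass
class PhaseCurrentMap:
    """Reconstructed complex field plus its real amplitude map on a 0-255 scale."""

    field: np.ndarray
    amplitude: np.ndarray
    scale: str = "minmax255"  # "minmax255" | "reference"
    gain: Optional[float] = None  # gain used for the reference scale

    def __post_init__(self):
        self.field = np.asarray(self.field, dtype=np.complex128)
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        if self.field.shape != self.amplitude.shape:
            raise ParameterError("field and amplitude shapes differ")
        if self.amplitude.min() < -1e-9 or self.amplitude.max() > AMPLITUDE_MAX + 1e-6:
            raise ParameterError("amplitude must lie in [0, 255]")

    @property
    def shape(self):
        return self.amplitude.shape


@dataclass
class OSHParams:
    """Parameters of the simulated OSH chain.

    filter_radius_frac is the circular stop-band radius as a fraction of the
    Nyquist frequency; values outside the stated 10-20 % band are allowed only
    with allow_out_of_band=True. k0 (wavenumber, 1/pixel) and z (propagation
    depth, pixels) apply to the FZP mode; their defaults put the central
    Fresnel zone at roughly 8 pixels (k0 * pixel^2 / 2z = 0.05 rad).
    """

    filter_radius_frac: float = DEFAULT_RADIUS_FRAC
    mode: str = "fourier_ppf"  # "fourier_ppf" | "fzp"
    scale: str = "minmax255"
    background_ref: Optional[PhaseCurrentMap] = None
    channel: str = "V"
    soft_edge: float = 0.0  # raised-cosine transition width (fraction of Nyquist)
    amplitude_sigma: float = 2.0  # Gaussian smoothing of |field| (speckle suppression)
    line_scan: bool = False  # row-wise 1-D FFT fidelity mode
    k0: float = 0.1
    z: float = 1.0
    allow_out_of_band: bool = False

    def __post_init__(self):
        lo, hi = RADIUS_FRAC_BAND
        if not self.allow_out_of_band and not (lo <= self.filter_radius_frac <= hi):
            raise ParameterError(
                f"filter_radius_frac {self.filter_radius_frac} outside [{lo}, {hi}] "
                "(set allow_out_of_band=True to override)")
        if self.mode not in ("fourier_ppf", "fzp"):
            raise ParameterError(f"unknown OSH mode {self.mode!r}")
        if self.mode == "fzp" and (self.k0 <= 0 or self.z <= 0):
            raise ParameterError("fzp mode requires k0 > 0 and z > 0")
        if self.scale not in ("minmax255", "reference"):
            raise ParameterError(f"unknown amplitude scale {self.scale!r}")


@dataclass
class FZPHologram:
    """Sine/cosine holograms and their complex combination h_cos + j h_sin."""

    h_sin: np.ndarray
    h_cos: np.ndarray
    h_complex: np.ndarray = dc_field(init=False)

    def __post_init__(self):
        self.h_sin = np.asarray(self.h_sin, dtype=np.float64)
        self.h_cos = np.asarray(self.h_cos, dtype=np.float64)
        self.h_complex = self.h_cos + 1j * self.h_sin


# ---------------------------------------------------------------------------
# Fourier / PPF chain
# ---------------------------------------------------------------------------

def forward_spectrum(img: RasterImage) -> Spectrum:
    """Centred 2-D DFT of a GRAY image."""
    if img.color_space != "GRAY":
        raise ParameterError("forward_spectrum needs a GRAY image")
    vals = np.fft.fftshift(np.fft.fft2(img.pixels))
    return Spectrum(values=vals, grid=img.shape)


def pure_phase_filter(spec: Spectrum, eps_rel: float = 1e-12) -> Spectrum:
    """Whiten the spectrum: each bin becomes value/|value|, tiny bins become 0.

    The guard threshold is eps_rel times the largest bin modulus.
    """
    mag = np.abs(spec.values)
    eps = eps_rel * (mag.max() if mag.size else 0.0)
    out = np.zeros_like(spec.values)
    keep = mag > eps
    out[keep] = spec.values[keep] / mag[keep]
    return Spectrum(values=out, grid=spec.grid)


def _normalized_radius(shape) -> np.ndarray:
    """Radial frequency with the Nyquist frequency of each axis mapped to 1."""
    h, w = shape
    fy = np.fft.fftshift(np.fft.fftfreq(h)) / 0.5
    fx = np.fft.fftshift(np.fft.fftfreq(w)) / 0.5
    return np.hypot.outer(fy, fx)


def circular_highpass(spec: Spectrum, radius_frac: float,
                      soft_edge: float = 0.0) -> Spectrum:
    """Zero all bins with normalised radial frequency below radius_frac.

    The stop band is a hard disk by default; soft_edge > 0 replaces the hard
    edge by a raised-cosine ramp of that width (fraction of Nyquist).
    """
    if not (0.0 < radius_frac < 1.0):
        raise ParameterError(f"radius_frac must lie in (0, 1), got {radius_frac}")
    rho = _normalized_radius(spec.values.shape)
    if soft_edge > 0.0:
        t = np.clip((rho - radius_frac) / soft_edge, 0.0, 1.0)
        window = 0.5 - 0.5 * np.cos(np.pi * t)
        window[rho < radius_frac] = 0.0
    else:
        window = (rho >= radius_frac).astype(np.float64)
    return Spectrum(values=spec.values * window, grid=spec.grid)


def inverse_reconstruct(spec: Spectrum) -> np.ndarray:
    """Centred inverse 2-D DFT; exact inverse of forward_spectrum."""
    return np.fft.ifft2(np.fft.ifftshift(spec.values))


#: Nominal cell radius of the white-disc calibration target, as a fraction of
#: the shorter image side (25 px at the standard 224 x 224 geometry).
CALIBRATION_RADIUS_FRAC = 25.0 / 224.0


def _calibration_target(shape) -> np.ndarray:
    """Centred white disc of nominal cell size on a black background."""
    h, w = shape
    radius = CALIBRATION_RADIUS_FRAC * min(h, w)
    yy, xx = np.ogrid[:h, :w]
    return ((yy - h // 2) ** 2 + (xx - w // 2) ** 2 <= radius ** 2).astype(np.float64)


def reference_gain(shape, radius_frac: float = DEFAULT_RADIUS_FRAC,
                   soft_edge: float = 0.0, amplitude_sigma: float = 0.0) -> float:
    """Gain anchoring the amplitude scale: a calibration white image -> 255.

    The calibration image is a white disc of nominal cell size (see
    :data:`CALIBRATION_RADIUS_FRAC`) on black: a perfectly opaque, perfectly
    coherent cell. Its peak through the PPF chain defines 255, so an image's
    amplitude measures how close its dominant object comes to that ideal;
    rare more-coherent inputs clip at 255.
    """
    h, w = shape
    target = _calibration_target((h, w))
    spec = Spectrum(np.fft.fftshift(np.fft.fft2(target)), (h, w))
    spec = pure_phase_filter(spec)
    spec = circular_highpass(spec, radius_frac, soft_edge)
    mag = np.abs(inverse_reconstruct(spec))
    if amplitude_sigma > 0:
        mag = gaussian_filter(mag, amplitude_sigma)
    peak = mag.max()
    if peak <= 0:
        raise ParameterError("degenerate calibration: stop band removed everything")
    return AMPLITUDE_MAX / peak


def phase_current_amplitude(field: np.ndarray, scale: str = "minmax255",
                            gain: Optional[float] = None,
                            amplitude_sigma: float = 0.0) -> PhaseCurrentMap:
    """Wrap a reconstructed field with its 0-255 amplitude map.

    minmax255 stretches |field| per image; reference multiplies |field| by a
    precomputed calibration gain (see :func:`reference_gain`) and clips.
    amplitude_sigma > 0 applies a Gaussian smoothing to |field| before
    rescaling — a speckle-robust amplitude estimate; the calibration gain
    must then be computed with the same smoothing.
    """
    field = np.asarray(field, dtype=np.complex128)
    if not np.all(np.isfinite(field)):
        raise ParameterError("field contains non-finite values")
    mag = np.abs(field)
    if amplitude_sigma > 0:
        mag = gaussian_filter(mag, amplitude_sigma)
    if scale == "minmax255":
        lo, hi = mag.min(), mag.max()
        amp = np.zeros_like(mag) if hi - lo < 1e-300 else (mag - lo) / (hi - lo) * AMPLITUDE_MAX
        return PhaseCurrentMap(field=field, amplitude=amp, scale=scale, gain=None)
    if scale == "reference":
        if gain is None:
            raise ParameterError("reference scale requires a calibration gain")
        amp = np.clip(mag * gain, 0.0, AMPLITUDE_MAX)
        return PhaseCurrentMap(field=field, amplitude=amp, scale=scale, gain=gain)
    raise ParameterError(f"unknown amplitude scale {scale!r}")


def subtract_background(pc_map: PhaseCurrentMap, ref: PhaseCurrentMap) -> PhaseCurrentMap:
    """Amplitude-domain background subtraction, clipped to [0, 255]."""
    if pc_map.shape != ref.shape:
        raise ParameterError(f"shape mismatch {pc_map.shape} vs {ref.shape}")
    amp = np.clip(pc_map.amplitude - ref.amplitude, 0.0, AMPLITUDE_MAX)
    return PhaseCurrentMap(field=pc_map.field.copy(), amplitude=amp,
                           scale=pc_map.scale, gain=pc_map.gain)


def _line_scan_field(pixels: np.ndarray, radius_frac: float) -> np.ndarray:
    """Row-wise 1-D variant of the chain (cylindrical-lens line scan fidelity)."""
    spec = np.fft.fftshift(np.fft.fft(pixels, axis=1), axes=1)
    mag = np.abs(spec)
    eps = 1e-12 * mag.max()
    out = np.zeros_like(spec)
    keep = mag > eps
    out[keep] = spec[keep] / mag[keep]
    fx = np.abs(np.fft.fftshift(np.fft.fftfreq(pixels.shape[1])) / 0.5)
    out[:, fx < radius_frac] = 0.0
    return np.fft.ifft(np.fft.ifftshift(out, axes=1), axis=1)


def phase_current_map(img: RasterImage, params: Optional[OSHParams] = None,
                      gain: Optional[float] = None) -> PhaseCurrentMap:
    """Full simulated OSH chain: forward -> PPF -> circular high-pass -> inverse.

    ``gain`` short-circuits the per-shape reference-gain calibration when the
    caller processes many same-shaped images.
    """
    params = params or OSHParams()
    if img.color_space != "GRAY":
        raise ParameterError("phase_current_map needs a GRAY image")
    if params.line_scan:
        field = _line_scan_field(img.pixels, params.filter_radius_frac)
    else:
        spec = forward_spectrum(img)
        spec = pure_phase_filter(spec)
        spec = circular_highpass(spec, params.filter_radius_frac, params.soft_edge)
        field = inverse_reconstruct(spec)
    if params.scale == "reference" and gain is None:
        gain = reference_gain(img.shape, params.filter_radius_frac,
                              params.soft_edge, params.amplitude_sigma)
    out = phase_current_amplitude(field, scale=params.scale, gain=gain,
                                  amplitude_sigma=params.amplitude_sigma)
    if params.background_ref is not None:
        out = subtract_background(out, params.background_ref)
    return out


# ---------------------------------------------------------------------------
# Fresnel-zone-plate hologram mode
# ---------------------------------------------------------------------------

def fzp_kernels(shape, k0: float, z: float):
    """Sampled sine/cosine Fresnel zone plates (k0/2 pi z) sin|cos(k0 r^2 / 2z)."""
    h, w = shape
    y = np.arange(h) - h // 2
    x = np.arange(w) - w // 2
    r2 = np.add.outer(y ** 2, x ** 2).astype(np.float64)
    phase = k0 * r2 / (2.0 * z)
    amp = k0 / (2.0 * np.pi * z)
    return amp * np.sin(phase), amp * np.cos(phase)


def fzp_hologram(img: RasterImage, params: OSHParams) -> FZPHologram:
    """Convolve the object intensity with the FZP chirp kernels (single plane)."""
    if params.mode != "fzp":
        raise ParameterError("fzp_hologram requires mode='fzp'")
    if img.color_space != "GRAY":
        raise ParameterError("fzp_hologram needs a GRAY image")
    ksin, kcos = fzp_kernels(img.shape, params.k0, params.z)
    h_sin = fftconvolve(img.pixels, ksin, mode="same")
    h_cos = fftconvolve(img.pixels, kcos, mode="same")
    return FZPHologram(h_sin=h_sin, h_cos=h_cos)
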