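# Methods

## The analysis chain

`holoseg` models the record-and-reconstruct cycle of optical scanning
holography (OSH) purely digitally. A blood-smear micrograph is reduced to a
single intensity plane (the V channel of HSV after per-image min–max
normalisation, inverted so the stained leukocyte is the bright object), and
the optical chain is simulated in the Fourier domain:

    field = IFFT( W_r · P( FFT(h) ) ),      P(H) = H / |H|

`P` is the pure phase filter (PPF): a correlation filter that keeps only the
spectral phase, acting as a whitening/edge-enhancing operator. Because the
filter is built from the spectrum of the input image itself, the chain is
template-free: the phase-only reconstruction concentrates energy at the
image's dominant coherent structure — the cell — and its linear phase ramp
encodes the cell position, so the modulus of the reconstructed field peaks
inside the cell. `W_r` is a hard circular stop-band (radius `r` as a fraction
of the Nyquist frequency, admissible 0.10–0.20, default 0.15, raised-cosine
edge optional) that removes illumination structure and the DC term. An
optional Fresnel-zone-plate mode convolves the object intensity with the
sine/cosine chirp kernels `(k0/2πz)·sin|cos(k0 r²/2z)` (defaults
`k0 = 0.1 px⁻¹`, `z = 1 px`, i.e. `k0/2z = 0.05 rad/px²`), reproducing the
sine/cosine holograms of a scanning system; the two modes are deliberately
kept separate.

### Amplitude scale

The classifier operates on a 0–255 "phase-current amplitude" scale. Two
scales are implemented:

* `minmax255` — per-image stretch of `|field|`; every image peaks at 255.
  Useful for visualisation, blind to inter-image contrast.
* `reference` (pipeline default) — `|field|` multiplied by a fixed gain
  calibrated once per image geometry on a **calibration white image**: a
  white disc of nominal cell radius (25 px at 224×224) on black, the
  idealised perfectly-opaque, perfectly-coherent cell, whose chain peak
  defines 255. The gain is shared by all images, so amplitude ordering is
  preserved across images; inputs more coherent than the calibration target
  clip at 255.

`|field|` is smoothed with a Gaussian of σ = 2 px before the maximum is
taken (`OSHParams.amplitude_sigma`). The raw per-image maximum rides on
speckle and scatters by ~4–6 % between statistically identical images;
the smoothed maximum scatters by roughly half that, which is what makes the
narrow class bands (e.g. [152, 165] vs [178, 186]) usable. The low-level
`phase_current_amplitude` operation defaults to σ = 0 (the plain modulus).

### Peak detection and automatic initialisation

The cell centre `C` is the argmax of the amplitude map after Gaussian
smoothing with σ = 10 px — roughly half the nominal cell radius, so
localisation behaves like a matched filter at cell scale; at the weakest
class contrast this lifts the in-cell localisation rate from ~80 % (σ = 2)
to ~100 %. The classification amplitude is always read from the *unsmoothed*
map. The initial contour `Ci` is the connected component containing `C` of
the half-rise region

    { A_smooth ≥ bg + 0.5 · (A_smooth(C) − bg) },   bg = median(A_smooth),

eroded one pixel (background-referencing reduces to the plain half-maximum
on clean maps but stays peak-local on speckled ones). A fixed disc of radius
10 px is the fallback when the region collapses. For multi-cell images,
`find_cell_peaks` applies non-maximum suppression at a minimum distance with
a relative amplitude threshold.

### Chan–Vese solver

Segmentation minimises the two-phase piecewise-constant energy

    E(φ) = μ·Length(φ) + λ₁ Σ_in (I−c₁)² + λ₂ Σ_out (I−c₂)²

with `c₁, c₂` the inside/outside means recomputed each iteration, `φ`
initialised as the signed distance to `Ci` (negative inside). The
implementation differs from textbook gradient flows in three ways, each
motivated by the requirement that the recorded energy history be genuinely
non-increasing:

* the energy actually descended is the smeared form — arctan Heaviside with
  width 1 px, and the length term written as the total variation of the
  smeared indicator — differentiated with the *matching discrete adjoint*.
  (The classical `δ(φ)·div(∇φ/|∇φ|)` force is not the gradient of any fixed
  discrete functional; under a monotone line search it stalls immediately.)
* steps are uniform-speed: `φ ← φ − dt·sign(∇E)` on pixels with non-trivial
  gradient, with `dt` (default 0.5 φ-units) halved under a backtracking line
  search that accepts only energy-decreasing steps (slack 1e-9). Magnitude
  steps make the interface speed scale with the squared class contrast, so
  low-contrast cells never converge within the iteration budget.
* signed-distance reinitialisation every 20 iterations is applied only when
  it does not raise the functional (it preserves the partition exactly).

Stopping: relative energy change below `tol` (default 1e-8) over a
5-iteration window, an inadmissible step, or `max_iter` (default 400). The
mask `{φ < 0}` then receives a discrete refinement: checkerboard sweeps of
single-pixel flips that strictly lower the hard-partition energy (exact
region sums plus an interface-count perimeter; checkerboard ordering makes
each flip's perimeter change exact). The pipeline additionally applies a
binary opening of radius 2 px (detaching thin spurious appendages), hole
filling, and keeps the connected component containing the seed centre.
Defaults `λ₁ = λ₂ = 1`, `μ = 0.2` on the [0, 1] intensity scale. The solver
is deterministic and, because `c₁/c₂` re-estimation makes the energy
invariant under `I → 1−I`, its output partition is identical on inverted
images.

The parametric snake (`α|v′|² + β|v″|²` internal energy, image energy
`−|∇I|` with central differences and bilinear sampling, semi-implicit
internal solve, optional balloon pressure) is provided as the alternative
formulation; Chan–Vese is the default because the stained cells are close to
homogeneous in intensity.

### Classification

Each class occupies a closed amplitude band; the published bands are the
defaults. `strict` policy returns `unclassified` for gap values (the bands do
not cover [0, 255]); `nearest` snaps to the closest band (ties to the
higher-amplitude class) for forced-choice evaluation. The decision tree over
the same bounds is implemented as an ordered threshold cascade and is
exhaustively identical to interval membership. Bands can be re-fitted from
labelled amplitudes by per-class min–max or symmetric quantiles; fitting
fails loudly if the fitted bands overlap. Box-plot statistics use the Tukey
convention (quartiles by linear interpolation, whiskers at the most extreme
points within 1.5 IQR).

### Evaluation

Pixel confusion counts feed sensitivity, specificity and Dice; the Hausdorff
distance is computed between *boundary* pixel sets (a contour-error measure;
filled-mask comparison available), with Euclidean metric in pixel units.
Dataset aggregation reports mean ± standard deviation. Classification
reports accuracy (%) and loss = 100 − accuracy, with `unclassified` counted
as incorrect.

## The phantom generator

Each phantom is a 224×224 RGB image: pink plasma background (0.97, 0.80,
0.85), 25–60 semi-transparent light-red erythrocyte discs (radius 7–13 px,
opacity 0.25–0.55), and one purple leukocyte — a radially perturbed ellipse
(radius 22.5–23.5 px, axis ratio ≥ 0.95, three harmonics of relative
amplitude ≤ 0.02) whose V-channel value is `1 − darkness`, with
class-dependent darkness plus Gaussian jitter (σ = 0.003) — then additive
Gaussian pixel noise (σ = 0.01) and clipping. The rasterised blob is the
exact ground-truth mask. A single spec-level seed spawns one child RNG
stream per image, so any subset is reproducible.

The class-to-darkness map (0.380 / 0.2431 / 0.1812 / 0.080) was set once by
bisection (`calibrate_contrast`) so the reference-scaled mean maximum
amplitudes land inside the four published bands, at targets 222 / 184 / 156 /
84.5 — inside each band but spaced to maximise pairwise gaps. Shape
variability is kept deliberately narrow: the per-image maximum amplitude
inherits ~3–4 units of scatter from shape and speckle alone, and the 13-unit
gap between the two middle bands leaves no room for broad size
distributions. This mirrors source material for this kind of study, where
per-class data are filtered to limit intra-class variability.

What the phantoms do *not* emulate: staining variation, touching/overlapping
leukocytes, nucleus/cytoplasm substructure, chromatic aberration, uneven
illumination. Passing the synthetic suite therefore demonstrates the
*mechanics* of the chain (localisation, seeding, convergence, interval
recovery) under controlled contrast/noise, not performance on real smears.

## Study conditions used by the tests and the acceptance script

* Segmentation quality: 50 single-cell phantoms (default mix of the four
  classes), OSH-initialised Chan–Vese, mean Dice and mean boundary Hausdorff
  reported; energy histories asserted non-increasing (1e-9 per step).
* Interval recovery: 80 phantoms per class split 40 train / 40 test;
  bands fitted on the training amplitudes by symmetric 2.5 % quantiles
  (robust to single extreme draws; with `nearest` classification the
  trimming does not affect accuracy); held-out accuracy and loss reported.
* Per-class mean amplitudes (`Amean`) reported on the test split.

These sizes keep the full suite and the acceptance run each within a few
minutes on one CPU while giving per-class samples comparable to the 100
images per class of the reference study design.

## Known limitations

* The reference amplitude scale depends on the calibration-disc radius; a
  different nominal cell size rescales all amplitudes and would require
  re-fitted intervals.
* The amplitude statistic conflates contrast with cell size and shape;
  phantoms exploit a narrow size range, and real data would need the
  documented interval re-fitting path.
* The line-scan (row-wise 1-D FFT) fidelity mode reconstructs per-row phase
  only; it is exposed for experimentation, not used by the default pipeline.
* `unclassified` is a first-class outcome under the strict policy; forced
  choice is opt-in.
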