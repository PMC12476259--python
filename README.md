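# holoseg

Automated classification and segmentation of leukemic cells in blood-smear
micrographs by **simulated optical scanning holography (OSH)** combined with
**active-contour segmentation**.

Peripheral-blood smears of suspected B-cell acute lymphoblastic leukemia
(B-ALL) contain one dominant leukocyte per field, graded into four classes:
*benign* (hematogones), *malignant-early* (early pre-B), *malignant-pre*
(pre-B) and *malignant-pro* (pro-B). `holoseg` implements a fully automated
analysis of such images:

1. **Preprocessing** — resize to 224×224, min–max normalisation to [0, 1],
   RGB→HSV conversion, V-channel selection, intensity inversion (the dark
   leukocyte becomes the bright dominant object).
2. **Simulated OSH phase reconstruction** — the image `h(x,y)` is transformed
   to its centred spectrum `H(u,v)`, whitened by a **pure phase filter**
   (every bin replaced by `H/|H|`), windowed by a circular high-pass with
   radius 10–20 % of the Nyquist frequency (default 15 %), and inverse
   transformed. The modulus of the reconstructed complex field — the
   *phase-current amplitude* — is mapped onto a 0–255 scale calibrated so a
   white disc of nominal cell size reaches 255.
3. **Automatic contour initialisation** — the global amplitude peak gives the
   cell centre `C` and peak amplitude `L`; the connected half-rise region
   around the peak, eroded one pixel, is the initial contour `Ci`. No manual
   seeding is needed.
4. **Chan–Vese segmentation** — a level-set minimisation of
   `μ·Length(φ) + λ₁·∫_inside (I−c₁)² + λ₂·∫_outside (I−c₂)²`
   seeded by `Ci`, with a monotone (energy-non-increasing) descent and a
   discrete refinement pass. A parametric snake
   (`E_int = α|v′|² + β|v″|²` plus a gradient-based image force) is also
   provided.
5. **Amplitude-interval classification** — each class occupies a disjoint
   closed band of maximum phase-current amplitude (benign [211, 227],
   malignant-early [178, 186], malignant-pre [152, 165], malignant-pro
   [80, 89]); classification is interval membership, equivalently an
   ordered-threshold decision tree. Bands can also be re-fitted from a
   labelled training set.
6. **Evaluation** — sensitivity TP/(TP+FN), specificity TN/(TN+FP), Dice
   2TP/(2TP+FP+FN) and the symmetric boundary Hausdorff distance, plus
   classification accuracy (%) and loss = 100 − accuracy.

A parametric **phantom generator** produces blood-smear-like images (pink
plasma, semi-transparent red-cell discs, one deformed-ellipse leukocyte with
class-dependent contrast) with exact ground-truth masks, so the entire chain
is testable without any external data. See `docs/methods.md` for the model,
parameter choices and limitations.

## Worked example

```bash
# generate a labelled synthetic dataset (2 images per class)
holoseg simulate --out demo/data --n-per-class 2 --seed 7

# run the full pipeline, fitting class intervals from the labels
holoseg run-all --manifest demo/data/manifest.csv --out demo/out --fit
```

which prints

```
wrote 8 samples under demo/data
stages ['phase+detect', 'segment', 'classify', 'evaluate']; artifacts in demo/out
```

and leaves per-image peak/amplitude tables (`amplitudes.csv`), masks
(`masks/*.png`), predictions (`predictions.csv`), fitted intervals
(`intervals.yaml`) and a `summary.json` like

```json
{
  "classification": {"accuracy_pct": 100.0, "loss_pct": 0.0, "n": 8},
  "segmentation": {
    "sensitivity": {"mean": 0.9994, "sd": 0.0012},
    "specificity": {"mean": 0.9978, "sd": 0.0056},
    "dice":        {"mean": 0.9729, "sd": 0.0664},
    "hausdorff":   {"mean": 2.1184, "sd": 4.1421},
    "n": 8
  }
}
```

Every classification here is correct, and the automatically initialised
Chan–Vese masks overlap the ground truth with mean Dice 0.97 and a mean
boundary error of ~2 px on this tiny demo set. `run_manifest.json` records
the full configuration and artifact hashes; rerunning with the same seed
reproduces the hashes bit-for-bit.

The same stages are available from Python (`holoseg.preprocess`,
`holoseg.phase_current_map`, `holoseg.find_global_peak`,
`holoseg.evolve_chan_vese`, `holoseg.classify_amplitude`, ...).

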