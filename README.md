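# phasekin

Image-analysis pipelines for **ligand-triggered solid–solid phase
transitions in RNA crystals**, built for two kinds of data:

* **Polarized video microscopy (PVM).** A birefringent crystal imaged
  between crossed polarizers loses transmitted intensity as its lattice
  converts. `phasekin` extracts per-pixel intensity traces
  *I(x, y, t)*, computes the negated derivative −∂I/∂t, detects and
  Gaussian-fits its peaks (transition **time** = fitted center,
  **duration** = half-width at half-max), classifies events into the
  transitions T1 < T2 < T3 by seeded k-means on (time, half-width), and
  quantifies spatiotemporal **synchrony** by resampling the region of
  interest at sampling areas of 1–90 pixels ("superpixels") and testing
  whether mean transition times depend on the sampling scale.
* **Atomic force microscopy (AFM).** Crystal-surface topographs are
  line-flattened, optionally denoised (FFT low-pass or correlation
  averaging), autocorrelated, and the in-plane unit-cell vectors are read
  off the most prominent autocorrelation peaks with sub-pixel and
  lattice-harmonic refinement. A c-axis time series labeled with the
  lattice phases (AUC 9.3 nm → TUC1 7.9 nm → TUC2 12.4 nm) summarizes the
  transition, including mixed-phase images measured region by region.

A first-class **synthetic-data module** generates both input types with
known ground truth — multiphasic logistic intensity decays
*I(t) = I₀·[1 − Σₖ aₖ·S((t − tₖ)/τₖ)] + ε* with per-pixel transition-time
jitter, and Gaussian-motif lattices with tilt, roughness and mixed-phase
regions — so every stage is testable by parameter recovery without any
external download.

## Worked example

```bash
python analysis/01_pvm_transition_kinetics.py --seed 1
```

generates a 90×90-pixel, 1550-frame synthetic video with the reference
transition structure and runs the full pipeline. It prints:

```
Detected 26575 transition events over 8100 pixels (1550 frames).
  T1: t = 227.0 +- 1.5 s, half-width 7.8 s, coverage 100% of pixels
  T2: t = 358.9 +- 20.0 s, half-width 11.0 s, coverage 99% of pixels
  T3: t = 416.0 +- 53.6 s, half-width 14.2 s, coverage 64% of pixels
  T1 synchrony: 90.8% of pixels transition within a 5 s window
  Center-pixel intensity loss: 49.9%
```

T1 is the sharp, highly synchronous first lattice conversion: its mean
detected time (227 s) recovers the designed center, >90% of pixels
convert within a 5-second window, and the total transmitted-intensity
loss is ~50%. The later, broader transitions carry larger spreads, and
the weakest step is only detected where it clears the amplitude
threshold (hence coverage < 100%).

The other drivers follow the same pattern:

* `analysis/02_pvm_scale_invariance.py` — transition time vs sampling
  area for a synchronous video (flat, the scale-invariance signature)
  against a 10-s spatial-gradient control (detected width grows with
  block side).
* `analysis/03_afm_lattice_transition.py` — a synthetic AFM sequence
  through the phases, including a three-region mixed image whose middle
  band measures ~12.5 nm, and the phase-labeled c-axis series.

Equivalent CLI verbs (`phasekin simulate-pvm|analyze-pvm|simulate-afm|
analyze-afm|report`) accept YAML/JSON configs; see `configs/`.

## Layout

```
src/phasekin/      library: synthetic, video, detect, synchrony, afm,
                   pipeline, cli
analysis/          numbered narrative drivers writing results/
scripts/           acceptance.py (headline-number reproduction)
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    model, parameter and design documentation
```
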