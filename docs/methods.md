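# Methods

## Signal model and front-end

The front-end converts a mono clip into a fixed-size time–frequency image.

**Pre-emphasis.** y[t] = x[t] − k·x[t−1] with k = 0.97 (first sample kept),
a first-order high-pass that compensates the low-frequency energy bias of
field recordings. Invertible given k and y[0].

**Windowing.** One Hann taper over the whole clip. The continuous wavelet
transform itself provides time localization, so no frame segmentation is
needed; the taper only suppresses edge transients interacting with the
zero-padded convolution boundary.

**CWT.** The complex Morlet ψ(t) = (π·f_b)^{−1/2} exp(j2π·f_c·t − t²/f_b)
with f_c = 1.0, f_b = 1.5 (a common complex-Morlet parameterization; both
exposed in `MorletParams`). Time is measured in samples, so a dilation α
corresponds to physical frequency f = f_c·f_s/α. The scale grid holds 112
geometrically spaced frequencies from 150 Hz up to 0.95 × Nyquist —
one grid row per image row, avoiding a second resampling axis. The
production path evaluates the transform by batched FFT convolution with
kernels truncated where the Gaussian envelope falls below 1e−8; a literal
O(n²) summation (`cwt_direct`) is kept as the validation reference and the
two agree to ~1e−9 relative in double precision. The pipeline renders with
a single-precision (complex64) transform: twice as fast, and after the
dynamic-range floor below the rendered pixels are identical to the double
path at 8-bit depth.

**Rendering.** 20·log10(|W| + 1e−10), clipped to the top 80 dB, min–max
normalized, bilinearly resampled to 112×112 and mapped through the "jet"
colormap (hot = energetic; configurable). The 80 dB floor is the one
deliberate refinement over plain min–max: without it the normalization is
pinned to the numerical noise floor of a near-silent region (−200 dB and
precision-dependent), whereas no real spectrogram information lives that
far below the peak. Rendering is invariant to positive rescaling of the
coefficients; a constant or all-zero scalogram renders uniformly with no
division by zero; row 0 is the highest frequency.

## Architectures

All models share one backbone on a 112×112×3 input: four same-padding
stride-1 conv layers (ReLU) with 64/64/32/32 filters, each followed by a
2×2 stride-2 max pool, then dropout 0.4, flatten (7·7·32 = 1568), dense
500 (ReLU), dense n_classes, softmax. Same padding is forced by the shape
trace: spatial extent must be halved by pools alone (112→56→28→14→7).

The kernel-decomposition rule splits an h×w kernel into the ordered
Cartesian set of floor/ceil halves; 5×5 → [2×2, 2×3, 3×2, 3×3]. The rule
is defined here for any h, w ≥ 2 as the minimal generalization of the 5×5
case; even dimensions produce duplicate members, which are kept so the set
always has four elements (one per conv layer or branch). CNN-SXX uses one
kernel shape throughout (the ablation baseline); MSCNN assigns the
decomposition set across its four conv layers in order; EMSCNN runs four
single-scale backbones in parallel and concatenates their flattened
features (6272) before a single shared dense-500/softmax head.

Two open choices were resolved as follows. The ensemble fuses after each
branch's flatten — equivalently its last pooled map — because the fusion
is specified as concatenating pooled intermediate results with softmax
applied once after concatenation; per-branch softmax heads would make the
shared head redundant. And the ensemble is trained end-to-end with a
single cross-entropy loss, the simplest consistent reading; per-branch
pre-training is out of scope.

`ModelSpec` is a declarative, JSON-serializable layer graph;
`propagate_shapes` and `parameter_count` are defined on the spec itself
and act as independent oracles for the realized network.

## Training

30 epochs by default, Adam with framework-default hyperparameters
(lr 1e−3, β₁ 0.9, β₂ 0.999), categorical cross-entropy, batch size 32 (a
package choice; the original protocol does not state one), stratified
80/20 split with floor rounding and at least one sample per class on each
side. No early stopping, LR schedule or augmentation. One integer seed
derives (via independent seed sequences) the corpus, the split shuffle,
weight initialization, batch order and dropout masks, so runs are
bit-reproducible on a given BLAS build.

The engine is a numpy CNN implementation: im2col convolution with
TensorFlow-style same padding (extra pad on bottom/right for even
kernels), 2×2/2 max pooling with floor halving and deterministic first-max
gradient routing, inverted dropout, fused softmax cross-entropy, manual
backprop verified against float64 central differences (agreement ~1e−6).
Float32 throughout; single-threaded.

## Synthetic corpus

Each species is a parametric signature: carrier frequency on a ladder with
guaranteed ≥ 300 Hz between-class spacing (base 3Δ, step 1.4Δ, jitter
±0.15Δ for spacing floor Δ = 300 Hz), a signed per-syllable linear FM
sweep (100–400 Hz), syllable length 80–200 ms with 20–120 ms gaps under a
Hann envelope, 1–3 harmonics with amplitude ratio 0.3–0.7, and white
Gaussian noise at 20 dB SNR. The harmonic count is capped so the top
partial stays below 90% of Nyquist; at 16 kHz roughly a dozen species fit
under that cap, so larger corpora need a higher sample rate. The default
test corpus is 5 species × 40 clips × 2 s at 16 kHz — small enough to
train the CNNs on one CPU core in minutes.

What the generator emulates: species-specific carriers, FM syllables,
repetition rhythm, harmonic stacks, broadband noise. What it does not:
amplitude-modulation texture, reverberation and habitat acoustics,
overlapping singers, within-species repertoire variation, recording-chain
artifacts. Consequently a passing end-to-end test shows the pipeline
learns genuinely class-separable time–frequency structure end to end; it
does not certify accuracy on real 30-species field recordings, which are
far less separable (real-data headline accuracies are in the ~90% range,
not the ~100% the synthetic corpus yields).

## Numerical and degenerate-input choices

- Convolution boundary: zero padding (symmetric edge effect).
- CWT kernel truncation at Gaussian envelope 1e−8; FFT path must match the
  direct sum to 1e−6 relative (tested at ~1e−9).
- Top-k ties broken toward the lower class index (deterministic).
- Per-class precision/recall with an empty denominator score 0 and are
  logged (conservative macro averaging).
- All-zero scalograms render uniformly; min–max degeneracy maps to 0.
- Pool on odd extents floors (7→3), matching the realized engine.
- Clip amplitudes are renormalized only if signal+noise exceeds ±1.

## Problem sizes used by the test suite and acceptance script

Unit tests run on miniature corpora (3 species × 6 clips × 0.5 s, 32×32
images) and small input shapes (16–32 px) for the engine oracles. The
end-to-end checks use the full default corpus (5 × 40 × 2 s, 112×112
images): MSCNN trained 10 epochs (it converges to ceiling within a few),
EMSCNN 3 epochs to demonstrate training and evaluation of the fused
model. These sizes are the package's chosen study conditions for CPU-scale
reproduction.

## Known limitations

- The engine is CPU-only and unoptimized relative to real frameworks
  (no vectorized multi-image augmentation, no GPU); it targets correctness
  and determinism, not throughput.
- The kernel-decomposition rule beyond 5×5 is this package's extension and
  not externally standardized.
- The synthetic corpus is intentionally easy; hyperparameters tuned on it
  (none are) would not transfer to field data.
- Reproducibility is bit-exact only on a fixed BLAS build; across builds,
  expect agreement to float32 rounding.
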