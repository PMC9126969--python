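# chirpnet

Bird species classification from song recordings, built around two ideas:

1. **Complex-Morlet wavelet scalograms** as the time–frequency front-end.
   A mono clip s(t) is pre-emphasized, Hann-tapered and transformed with

       W(α, β) = (1/√α) ∫ s(t) ψ*((t − β)/α) dt,
       ψ(t) = (1/√(π·f_b)) · exp(j·2π·f_c·t − t²/f_b),

   where α (dilation) maps to physical frequency f = f_c·f_s/α and β is the
   time shift. |W| is log-compressed and rendered as a 112×112×3 colour
   image (hotter colour = more energy). The wavelet's adaptive
   time–frequency window suits the fast frequency modulation of birdsong
   better than a fixed-window STFT.

2. **Multi-scale convolution kernels** obtained by decomposing one base
   kernel into the Cartesian set of its floor/ceil halves,

       5×5  →  [2×2, 2×3, 3×2, 3×3],

   used two ways on a shared backbone (conv 64/64/32/32 + 2×2 pools +
   dropout 0.4 + flatten 1568 → dense 500 → softmax):

   * **MSCNN** — one network, conv layer *i* uses the *i*-th kernel of the
     set;
   * **EMSCNN** — four parallel single-scale backbones whose flattened
     features (4 × 1568 = 6272) are concatenated before one shared
     dense + softmax head.

A seeded synthetic-birdsong generator (species-specific carriers ≥ 300 Hz
apart, FM syllables with harmonics, Gaussian noise at a configurable SNR)
makes the whole pipeline testable offline; real recordings drop in via the
same directory-per-class WAV/PNG layout. The CNN engine itself is a small,
fully tested numpy implementation (im2col convolution, Adam, backprop), so
the package has no deep-learning-framework dependency and every run is
bit-reproducible from one seed.

## Worked example

```python
from chirpnet import (
    ExperimentConfig, run_experiment,
    decompose_kernel, build_mscnn, propagate_shapes,
)
from chirpnet.pipeline import ModelChoice
from chirpnet.training import TrainConfig

print(decompose_kernel((5, 5)).as_tuples())
# [(2, 2), (2, 3), (3, 2), (3, 3)]

trace = propagate_shapes(build_mscnn(decompose_kernel((5, 5)), 30))
print(trace.flatten_length)   # 1568  (7*7*32 after four pools of 112)

cfg = ExperimentConfig(out_dir="scratch/demo", seed=1,
                       model=ModelChoice(kind="mscnn"),
                       train=TrainConfig(epochs=15, seed=1))
report = run_experiment(cfg)    # synthesizes 5x40 clips, renders, trains
print(report.model_name, round(report.accuracy, 3), round(report.top5, 3))
# MSCNN 1.0 1.0
```

On the default synthetic corpus (5 species × 40 clips × 2 s at 16 kHz,
20 dB SNR) the MSCNN separates all five classes within a few epochs —
validation accuracy 1.000 — because the generator's carrier spacing makes
the scalogram ridges highly discriminable; real 30-species corpora are far
harder (see `docs/methods.md`).

Or from the shell:

```bash
chirpnet decompose 5x5
chirpnet synth --n-species 5 --out-dir scratch/audio
chirpnet spectrogram --audio-dir scratch/audio --out-dir scratch/images
chirpnet run --out-dir scratch/exp --seed 1 --model mscnn --epochs 15
chirpnet compare --out-dir scratch/cmp --seed 1 --models cnn_s22,mscnn,emscnn
```

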