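import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_corpus(tmp_path_factory):
    """A small synthetic WAV corpus: 3 species x 6 clips x 0.5 s at 16 kHz."""
    from chirpnet.synthetic_audio import generate_dataset

    root = tmp_path_factory.mktemp("corpus")
    manifest = generate_dataset(
        n_species=3,
        clips_per_species=6,
        duration_s=0.5,
        sample_rate=16000.0,
        rng_seed=11,
        out_dir=root,
    )
    return manifest


@pytest.fixture(scope="session")
def tiny_images(tiny_corpus, tmp_path_factory):
    """32x32 scalogram PNGs of the tiny corpus."""
    from pathlib import Path

    from chirpnet.pipeline import spectrogram_stage
    from chirpnet.wavelet import SpectrogramConfig

    out = tmp_path_factory.mktemp("images")
    cfg = SpectrogramConfig(height=32, width=32)
    return spectrogram_stage(tiny_corpus, Path(out), cfg)


@pytest.fixture
def toy_separable():
    """Trivially separable 2-class image set: all-dark vs all-bright."""
    rng = np.random.default_rng(5)
    n_per = 24
    dark = rng.uniform(0.0, 0.15, size=(n_per, 16, 16, 3))
    bright = rng.uniform(0.85, 1.0, size=(n_per, 16, 16, 3))
    x = np.concatenate([dark, bright]).astype(np.float32)
    y = np.array([0] * n_per + [1] * n_per)
    order = rng.permutation(2 * n_per)
    return x[order], y[order]
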