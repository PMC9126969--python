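"""End-to-end orchestration: synthesis → spectrograms → training → evaluation.

One :class:`ExperimentConfig` (YAML-serializable) and one seed drive every
stage: corpus generation, spectrogram rendering (cached as PNGs in a
directory-per-class layout, so real recordings can be dropped in with the
same structure), the stratified split, model construction, training and
the metric report.  Stage failures are re-raised as
:class:`PipelineStageError` naming the stage; artifacts written by earlier
stages are retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from chirpnet.evaluation import EvalReport, evaluate_predictions
from chirpnet.kernels import KernelShape, decompose_kernel
from chirpnet.models import ModelSpec, build_cnn_sxx, build_emscnn, build_mscnn
from chirpnet.synthetic_audio import DatasetManifest, generate_dataset
from chirpnet.training import (
    TrainConfig,
    load_images,
    predict_proba,
    save_checkpoint,
    split_dataset,
    train,
)
from chirpnet.wavelet import SpectrogramConfig, read_wav, save_png, waveform_to_image

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SynthConfig:
    """Default corpus: 5 species x 40 clips x 2 s at 16 kHz, 20 dB SNR."""

    n_species: int = 5
    clips_per_species: int = 40
    duration_s: float = 2.0
    sample_rate: float = 16000.0
    snr_db: float = 20.0

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        return cls(**d)


@dataclass
class ModelChoice:
    """Which architecture to build: cnn_sxx / mscnn / emscnn plus its kernel.

    ``kernel`` is the conv kernel of a single-scale model, or the base
    kernel whose decomposition supplies the multi-scale set / the four
    ensemble branches.  ``branch_kernels`` overrides the decomposition for
    emscnn (e.g. the homogeneous-kernel ensemble ablation).
    """

    kind: str = "mscnn"
    kernel: tuple[int, int] = (5, 5)
    branch_kernels: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("cnn_sxx", "mscnn", "emscnn"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind in ("mscnn",) or (self.kind == "emscnn" and self.branch_kernels is None):
            h, w = self.kernel
            if h < 2 or w < 2:
                raise ValueError(f"{self.kind} needs a decomposable base kernel, got {h}x{w}")

    @classmethod
    def parse(cls, text: str) -> "ModelChoice":
        """Parse names like ``cnn_s23``, ``mscnn``, ``emscnn``, ``emscnn_s55``."""
        text = text.strip().lower()
        if text == "mscnn":
            return cls(kind="mscnn")
        if text == "emscnn":
            return cls(kind="emscnn")
        for prefix, kind in (("cnn_s", "cnn_sxx"), ("emscnn_s", "emscnn")):
            if text.startswith(prefix) and len(text) == len(prefix) + 2:
                h, w = int(text[-2]), int(text[-1])
                if kind == "emscnn":
                    return cls(kind=kind, kernel=(h, w), branch_kernels=[(h, w)] * 4)
                return cls(kind=kind, kernel=(h, w))
        raise ValueError(f"cannot parse model choice {text!r}")

    def build(self, n_classes: int, input_shape) -> ModelSpec:
        if self.kind == "cnn_sxx":
            return build_cnn_sxx(self.kernel, n_classes, input_shape)
        if self.kind == "mscnn":
            return build_mscnn(decompose_kernel(KernelShape(*self.kernel)), n_classes, input_shape)
        branch = self.branch_kernels or decompose_kernel(KernelShape(*self.kernel)).as_tuples()
        return build_emscnn(branch, n_classes, input_shape)

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "kernel": list(self.kernel)}
        if self.branch_kernels is not None:
            d["branch_kernels"] = [list(k) for k in self.branch_kernels]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelChoice":
        d = dict(d)
        d["kernel"] = tuple(d.get("kernel", (5, 5)))
        if d.get("branch_kernels") is not None:
            d["branch_kernels"] = [tuple(k) for k in d["branch_kernels"]]
        return cls(**d)


@dataclass
class ExperimentConfig:
    """Everything needed to replay one experiment from a single seed."""

    out_dir: str = "experiment"
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    audio_dir: str | None = None  # pre-existing WAV corpus (skips synthesis)
    image_dir: str | None = None  # pre-rendered PNGs (skips synthesis + spectrograms)
    spectrogram: SpectrogramConfig = field(default_factory=SpectrogramConfig)
    model: ModelChoice = field(default_factory=ModelChoice)
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "synth": self.synth.to_dict(),
            "audio_dir": self.audio_dir,
            "image_dir": self.image_dir,
            "spectrogram": self.spectrogram.to_dict(),
            "model": self.model.to_dict(),
            "train": self.train.to_dict(),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "synth" in d:
            d["synth"] = SynthConfig.from_dict(d["synth"])
        if "spectrogram" in d:
            d["spectrogram"] = SpectrogramConfig.from_dict(d["spectrogram"])
        if "model" in d:
            d["model"] = ModelChoice.from_dict(d["model"])
        if "train" in d:
            d["train"] = TrainConfig.from_dict(d["train"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _scan_directory(root: Path, suffix: str) -> DatasetManifest:
    classes = sorted(p.name for p in root.iterdir() if p.is_dir())
    if len(classes) < 2:
        raise ValueError(f"{root} must contain at least 2 class subdirectories")
    entries = []
    for label, name in enumerate(classes):
        files = sorted((root / name).glob(f"*{suffix}"))
        if not files:
            raise ValueError(f"class directory {root / name} holds no {suffix} files")
        entries.extend((str(f), label) for f in files)
    return DatasetManifest(entries=entries, class_names=classes)


def spectrogram_stage(
    audio_manifest: DatasetManifest, out_dir: Path, cfg: SpectrogramConfig
) -> DatasetManifest:
    """Render every WAV of the manifest to a PNG, mirrored dir-per-class.

    Deterministic: rerunning with an unchanged config rewrites identical
    bytes, so cached images can be trusted across stages.
    """
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for path, label in audio_manifest.entries:
        cls_dir = out_dir / audio_manifest.class_names[label]
        cls_dir.mkdir(exist_ok=True)
        png = cls_dir / (Path(path).stem + ".png")
        image = waveform_to_image(read_wav(path), cfg)
        save_png(image, png)
        entries.append((str(png), label))
    return DatasetManifest(entries=entries, class_names=list(audio_manifest.class_names))


def _prepare_images(config: ExperimentConfig) -> DatasetManifest:
    out = Path(config.out_dir)
    if config.image_dir is not None:
        return _scan_directory(Path(config.image_dir), ".png")
    try:
        if config.audio_dir is not None:
            audio_manifest = _scan_directory(Path(config.audio_dir), ".wav")
        else:
            audio_manifest = generate_dataset(
                n_species=config.synth.n_species,
                clips_per_species=config.synth.clips_per_species,
                duration_s=config.synth.duration_s,
                sample_rate=config.synth.sample_rate,
                rng_seed=config.seed,
                out_dir=out / "audio",
                snr_db=config.synth.snr_db,
            )
    except Exception as exc:
        raise PipelineStageError("synthesis", exc) from exc
    try:
        return spectrogram_stage(audio_manifest, out / "spectrograms", config.spectrogram)
    except Exception as exc:
        raise PipelineStageError("spectrogram", exc) from exc


def _train_and_evaluate(
    config: ExperimentConfig,
    spec: ModelSpec,
    splits,
    out: Path,
    tag: str,
) -> EvalReport:
    train_manifest, val_manifest = splits
    try:
        x_train, y_train = load_images(train_manifest)
        x_val, y_val = load_images(val_manifest)
        net, history = train(spec, (x_train, y_train), (x_val, y_val), config.train)
        out.mkdir(parents=True, exist_ok=True)
        history.to_csv(out / f"{tag}_history.csv")
        save_checkpoint(net, out / f"{tag}_weights.npz", out / f"{tag}_spec.json")
    except Exception as exc:
        raise PipelineStageError("train", exc) from exc
    try:
        proba = predict_proba(net, x_val)
        report = evaluate_predictions(proba, y_val, spec.n_classes, model_name=spec.name)
        report.to_json(out / f"{tag}_report.json")
    except Exception as exc:
        raise PipelineStageError("evaluate", exc) from exc
    return report


def run_experiment(config: ExperimentConfig) -> EvalReport:
    """Execute the full pipeline and return the validation report.

    Writes, under ``config.out_dir``: the audio corpus (if synthesized),
    the spectrogram PNGs, the split manifests, the training history CSV,
    the weight checkpoint + ModelSpec JSON, the report JSON, and the
    resolved config YAML.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    image_manifest = _prepare_images(config)
    try:
        splits = split_dataset(image_manifest, config.train)
        splits[0].to_csv(out / "train_manifest.csv")
        splits[1].to_csv(out / "val_manifest.csv")
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("split", exc) from exc
    input_shape = (config.spectrogram.height, config.spectrogram.width, 3)
    spec = config.model.build(len(image_manifest.class_names), input_shape)
    report = _train_and_evaluate(config, spec, splits, out, spec.name.lower())
    logger.info("experiment done: %s accuracy %.3f", spec.name, report.accuracy)
    return report


def compare_models(config: ExperimentConfig, model_choices: list) -> "pd.DataFrame":
    """Train several architectures on one shared corpus, images and split.

    All models see byte-identical train/validation partitions and the same
    training seed; returns (and writes) a table with one row per model and
    the six headline metrics.
    """
    import pandas as pd

    if len(model_choices) < 2:
        raise ValueError("compare_models needs at least 2 model choices")
    choices = [c if isinstance(c, ModelChoice) else ModelChoice.parse(c) for c in model_choices]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    image_manifest = _prepare_images(config)
    try:
        splits = split_dataset(image_manifest, config.train)
    except Exception as exc:
        raise PipelineStageError("split", exc) from exc
    input_shape = (config.spectrogram.height, config.spectrogram.width, 3)
    rows = []
    for choice in choices:
        spec = choice.build(len(image_manifest.class_names), input_shape)
        report = _train_and_evaluate(config, spec, splits, out, spec.name.lower())
        rows.append(
            {
                "Model": spec.name,
                "Accuracy": report.accuracy,
                "Precision": report.precision_macro,
                "Recall": report.recall_macro,
                "F1-score": report.f1_macro,
                "Top-1": report.top1,
                "Top-5": report.top5,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out / "comparison.csv", index=False)
    return table


def report_to_json_dict(report: EvalReport) -> dict:
    return report.to_dict()


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
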