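"""Declarative CNN architectures: single-scale CNN-SXX, MSCNN and EMSCNN.

All three share one backbone (four conv layers with 64/64/32/32 filters,
each followed by 2x2 stride-2 max pooling, then dropout 0.4, flatten,
dense 500 with ReLU, and a softmax head over the classes) applied to a
112x112x3 spectrogram image, differing only in where kernel shapes vary:

* CNN-SXX — every conv layer uses the same h x w kernel ("XX" names it,
  e.g. CNN-S23 for 2x3).
* MSCNN — conv layer i uses the i-th member of a decomposition set, so one
  network sees the image at four kernel scales in sequence.
* EMSCNN — four parallel single-scale backbones (one kernel shape each) are
  run on the same input; their flattened features are concatenated and a
  single shared dense+softmax head produces the prediction.

A ``ModelSpec`` is a framework-agnostic layer-graph description; shape
propagation (:func:`propagate_shapes`) and parameter counting are defined
on the spec itself, and the numpy engine in :mod:`chirpnet.nn` realizes it
for training.  Convolutions use "same" padding with stride 1 — the only
choice consistent with a trace whose spatial size is halved by pools alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import prod

from chirpnet.kernels import KernelShape, KernelSet

DEFAULT_INPUT_SHAPE = (112, 112, 3)
_BACKBONE_FILTERS = (64, 64, 32, 32)
_DENSE_UNITS = 500
_DROPOUT_RATE = 0.4


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a network description."""

    kind: str  # input | conv | maxpool | dropout | flatten | dense | concat | softmax
    kernel: tuple[int, int] | None = None
    stride: int = 1
    filters: int | None = None
    units: int | None = None
    rate: float | None = None
    padding: str = "same"
    activation: str | None = None

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        for k in ("kernel", "stride", "filters", "units", "rate", "padding", "activation"):
            v = getattr(self, k)
            if v is not None and not (k == "stride" and v == 1) and not (k == "padding" and v == "same"):
                d[k] = list(v) if k == "kernel" else v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LayerSpec":
        d = dict(d)
        if "kernel" in d and d["kernel"] is not None:
            d["kernel"] = tuple(d["kernel"])
        return cls(**d)


@dataclass
class ModelSpec:
    """A sequential network (``layers``) or a multi-branch one (``branches`` + ``head``)."""

    name: str
    n_classes: int
    input_shape: tuple[int, int, int] = DEFAULT_INPUT_SHAPE
    layers: list[LayerSpec] | None = None
    branches: list[list[LayerSpec]] | None = None
    head: list[LayerSpec] | None = None

    def __post_init__(self) -> None:
        if (self.layers is None) == (self.branches is None):
            raise ValueError("a ModelSpec has either layers or branches, not both")
        if self.branches is not None and self.head is None:
            raise ValueError("a branched ModelSpec needs a fusion head")

    @property
    def is_branched(self) -> bool:
        return self.branches is not None

    def conv_kernels(self) -> list[tuple[int, int]]:
        """Kernel shapes of the conv layers (sequential models only)."""
        if self.is_branched:
            raise ValueError("conv_kernels is defined for sequential models")
        return [l.kernel for l in self.layers if l.kind == "conv"]

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "n_classes": self.n_classes,
            "input_shape": list(self.input_shape),
        }
        if self.layers is not None:
            d["layers"] = [l.to_dict() for l in self.layers]
        else:
            d["branches"] = [[l.to_dict() for l in br] for br in self.branches]
            d["head"] = [l.to_dict() for l in self.head]
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        kwargs = {
            "name": d["name"],
            "n_classes": d["n_classes"],
            "input_shape": tuple(d["input_shape"]),
        }
        if "layers" in d:
            kwargs["layers"] = [LayerSpec.from_dict(x) for x in d["layers"]]
        else:
            kwargs["branches"] = [[LayerSpec.from_dict(x) for x in br] for br in d["branches"]]
            kwargs["head"] = [LayerSpec.from_dict(x) for x in d["head"]]
        return cls(**kwargs)

    @classmethod
    def from_json(cls, text_or_path) -> "ModelSpec":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


def _as_kernel(k) -> tuple[int, int]:
    if isinstance(k, KernelShape):
        return k.as_tuple()
    h, w = k
    return (int(h), int(w))


def _backbone_layers(kernels: list[tuple[int, int]]) -> list[LayerSpec]:
    """conv/pool x4 + dropout + flatten, one kernel shape per conv layer."""
    layers: list[LayerSpec] = []
    for kernel, filters in zip(kernels, _BACKBONE_FILTERS):
        layers.append(LayerSpec("conv", kernel=kernel, filters=filters, activation="relu"))
        layers.append(LayerSpec("maxpool", kernel=(2, 2), stride=2))
    layers.append(LayerSpec("dropout", rate=_DROPOUT_RATE))
    layers.append(LayerSpec("flatten"))
    return layers


def _head_layers(n_classes: int) -> list[LayerSpec]:
    return [
        LayerSpec("dense", units=_DENSE_UNITS, activation="relu"),
        LayerSpec("dense", units=n_classes),
        LayerSpec("softmax"),
    ]


def build_cnn_sxx(
    kernel,
    n_classes: int,
    input_shape: tuple[int, int, int] = DEFAULT_INPUT_SHAPE,
    name: str | None = None,
) -> ModelSpec:
    """Single-scale baseline: the shared backbone with one kernel shape throughout."""
    k = _as_kernel(kernel)
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    layers = [LayerSpec("input")] + _backbone_layers([k] * 4) + _head_layers(n_classes)
    return ModelSpec(
        name=name or f"CNN-S{k[0]}{k[1]}",
        n_classes=n_classes,
        input_shape=tuple(input_shape),
        layers=layers,
    )


def build_mscnn(
    kernels: KernelSet | list,
    n_classes: int,
    input_shape: tuple[int, int, int] = DEFAULT_INPUT_SHAPE,
) -> ModelSpec:
    """Multi-scale CNN: conv layer i uses the i-th kernel of the decomposition set."""
    ks = [_as_kernel(k) for k in kernels]
    if len(ks) != 4:
        raise ValueError(f"MSCNN needs exactly 4 kernels (one per conv layer), got {len(ks)}")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    layers = [LayerSpec("input")] + _backbone_layers(ks) + _head_layers(n_classes)
    return ModelSpec(
        name="MSCNN", n_classes=n_classes, input_shape=tuple(input_shape), layers=layers
    )


def build_emscnn(
    branch_kernels: KernelSet | list,
    n_classes: int,
    input_shape: tuple[int, int, int] = DEFAULT_INPUT_SHAPE,
) -> ModelSpec:
    """Ensemble multi-scale CNN: four single-scale backbones fused by concatenation.

    Branch i is the full conv/pool/dropout/flatten stack of the single-scale
    baseline with ``branch_kernels[i]``; the four flattened feature vectors
    are concatenated and classified by one shared dense-500/softmax head.
    Homogeneous kernel lists (the single-scale ensemble ablation) are valid.
    """
    ks = [_as_kernel(k) for k in branch_kernels]
    if len(ks) != 4:
        raise ValueError(f"EMSCNN needs exactly 4 branch kernels, got {len(ks)}")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    branches = [_backbone_layers([k] * 4) for k in ks]
    head = [LayerSpec("concat")] + _head_layers(n_classes)
    return ModelSpec(
        name="EMSCNN",
        n_classes=n_classes,
        input_shape=tuple(input_shape),
        branches=branches,
        head=head,
    )


@dataclass
class ShapeTrace:
    """Per-layer output shapes; tuples are (h, w, c) or (length,) after flatten."""

    entries: list[tuple[str, tuple]] = field(default_factory=list)

    def shapes(self) -> list[tuple]:
        return [s for _, s in self.entries]

    def spatial_sizes(self) -> list[int]:
        """Heights of all spatially-resolved stages, pools included once each."""
        return [s[0] for _, s in self.entries if len(s) == 3]

    @property
    def flatten_length(self) -> int:
        flats = [s[0] for name, s in self.entries if name.endswith("flatten")]
        if not flats:
            raise ValueError("trace contains no flatten layer")
        return flats[-1]

    @property
    def concat_length(self) -> int:
        lens = [s[0] for name, s in self.entries if name.endswith("concat")]
        if not lens:
            raise ValueError("trace contains no concat layer")
        return lens[-1]

    @property
    def output_width(self) -> int:
        return self.entries[-1][1][0]


def _propagate_sequential(
    layers: list[LayerSpec], shape: tuple, prefix: str, trace: ShapeTrace
) -> tuple:
    for i, layer in enumerate(layers):
        label = f"{prefix}{i}:{layer.kind}"
        if layer.kind == "input":
            pass
        elif layer.kind == "conv":
            if layer.padding != "same" or layer.stride != 1:
                raise ValueError(f"{label}: only same-padding stride-1 conv is supported")
            h, w, _ = shape
            shape = (h, w, layer.filters)
        elif layer.kind == "maxpool":
            h, w, c = shape
            shape = (h // 2, w // 2, c)
            if shape[0] < 1 or shape[1] < 1:
                raise ValueError(f"{label}: spatial extent collapsed to {shape[:2]}")
        elif layer.kind == "dropout":
            pass
        elif layer.kind == "flatten":
            shape = (prod(shape),)
        elif layer.kind == "dense":
            shape = (layer.units,)
        elif layer.kind == "softmax":
            pass
        else:
            raise ValueError(f"{label}: unknown layer kind {layer.kind!r}")
        trace.entries.append((label, shape))
    return shape


def propagate_shapes(spec: ModelSpec, input_shape: tuple | None = None) -> ShapeTrace:
    """Walk the layer graph and record every output extent.

    Same-padding convs preserve the spatial size; 2x2 stride-2 pools halve
    it with floor rounding; flatten multiplies out; concat sums branch
    flatten lengths.  Raises if any extent becomes non-positive, naming the
    offending layer.
    """
    shape = tuple(input_shape or spec.input_shape)
    trace = ShapeTrace()
    trace.entries.append(("input", shape))
    if not spec.is_branched:
        _propagate_sequential(spec.layers, shape, "", trace)
        return trace
    feat_lengths = []
    for b, branch in enumerate(spec.branches):
        out = _propagate_sequential(branch, shape, f"branch{b}/", trace)
        if len(out) != 1:
            raise ValueError(f"branch {b} must end flattened, got shape {out}")
        feat_lengths.append(out[0])
    head_shape: tuple = (sum(feat_lengths),)
    for i, layer in enumerate(spec.head):
        label = f"head{i}:{layer.kind}"
        if layer.kind == "concat":
            pass
        elif layer.kind == "dense":
            head_shape = (layer.units,)
        elif layer.kind == "softmax":
            pass
        else:
            raise ValueError(f"{label}: unsupported head layer {layer.kind!r}")
        trace.entries.append((label, head_shape))
    return trace


def parameter_count(spec: ModelSpec, input_shape: tuple | None = None) -> int:
    """Closed-form trainable parameter count implied by the spec.

    conv: (kh·kw·c_in + 1)·filters; dense: (fan_in + 1)·units; other layers
    carry no parameters.  Serves as the independent check on the realized
    network.
    """
    shape = tuple(input_shape or spec.input_shape)

    def count_sequential(layers: list[LayerSpec], shape: tuple) -> tuple[int, tuple]:
        total = 0
        for layer in layers:
            if layer.kind == "conv":
                kh, kw = layer.kernel
                total += (kh * kw * shape[2] + 1) * layer.filters
                shape = (shape[0], shape[1], layer.filters)
            elif layer.kind == "maxpool":
                shape = (shape[0] // 2, shape[1] // 2, shape[2])
            elif layer.kind == "flatten":
                shape = (prod(shape),)
            elif layer.kind == "dense":
                total += (shape[0] + 1) * layer.units
                shape = (layer.units,)
        return total, shape

    if not spec.is_branched:
        total, _ = count_sequential(spec.layers, shape)
        return total
    total = 0
    feat = 0
    for branch in spec.branches:
        t, out = count_sequential(branch, shape)
        total += t
        feat += out[0]
    t, _ = count_sequential(spec.head, (feat,))
    return total + t
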