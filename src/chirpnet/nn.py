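"""A small CPU CNN engine on numpy: layers, backprop, Adam.

Realizes a :class:`~chirpnet.models.ModelSpec` as a trainable network.
Convolution is im2col + matrix multiply with TensorFlow-style "same"
padding (total pad = k − 1, the extra row/column on the bottom/right);
max pooling is 2x2 stride 2 with floor halving and deterministic
first-maximum gradient routing.  Forward passes return logits; softmax is
applied by the loss (fused softmax cross-entropy) or by
:func:`Network.predict_proba`.

Everything is float32 and seeded through a single ``numpy`` Generator, so
training runs are bit-reproducible on a given BLAS build.
"""

from __future__ import annotations

import numpy as np

from chirpnet.models import LayerSpec, ModelSpec

#: Module-wide compute dtype.  float32 is the production default; tests may
#: rebind to float64 for high-precision gradient validation.
DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _same_pads(k: int) -> tuple[int, int]:
    total = k - 1
    return total // 2, total - total // 2


class Conv2D:
    """Same-padding stride-1 convolution with optional fused ReLU."""

    def __init__(self, kernel, c_in, filters, rng, activation="relu"):
        kh, kw = kernel
        self.kh, self.kw, self.c_in, self.filters = kh, kw, c_in, filters
        self.activation = activation
        fan_in = kh * kw * c_in
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, filters)).astype(DTYPE))
        self.b = Param(np.zeros(filters, dtype=DTYPE))

    def params(self):
        return [self.W, self.b]

    def _im2col(self, xp, h, w):
        n = xp.shape[0]
        cols = np.empty((n, h, w, self.kh * self.kw * self.c_in), dtype=DTYPE)
        idx = 0
        for i in range(self.kh):
            for j in range(self.kw):
                cols[..., idx : idx + self.c_in] = xp[:, i : i + h, j : j + w, :]
                idx += self.c_in
        return cols

    def forward(self, x, train=False):
        n, h, w, _ = x.shape
        pt, pb = _same_pads(self.kh)
        pl, pr = _same_pads(self.kw)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        cols = self._im2col(xp, h, w)
        z = cols.reshape(-1, cols.shape[-1]) @ self.W.value + self.b.value
        z = z.reshape(n, h, w, self.filters)
        if self.activation == "relu":
            out = np.maximum(z, 0.0)
            self._mask = z > 0
        else:
            out = z
            self._mask = None
        self._cols = cols
        self._in_shape = x.shape
        return out

    def backward(self, dout):
        if self._mask is not None:
            dout = dout * self._mask
        n, h, w, f = dout.shape
        dflat = dout.reshape(-1, f)
        colsf = self._cols.reshape(-1, self._cols.shape[-1])
        self.W.grad += colsf.T @ dflat
        self.b.grad += dflat.sum(axis=0)
        dcols = (dflat @ self.W.value.T).reshape(self._cols.shape)
        pt, pb = _same_pads(self.kh)
        pl, pr = _same_pads(self.kw)
        _, hin, win, c = self._in_shape
        dxp = np.zeros((n, hin + pt + pb, win + pl + pr, c), dtype=DTYPE)
        idx = 0
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i : i + h, j : j + w, :] += dcols[..., idx : idx + c]
                idx += c
        self._cols = None
        return dxp[:, pt : pt + hin, pl : pl + win, :]


class MaxPool2D:
    """2x2 stride-2 max pooling, floor halving, first-max tie-break."""

    def params(self):
        return []

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : 2 * h2, : 2 * w2, :]
        windows = (
            xc.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h2, w2, 4, c)
        )
        self._argmax = windows.argmax(axis=3)
        out = np.take_along_axis(windows, self._argmax[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        self._in_shape = x.shape
        return out

    def backward(self, dout):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dwin = np.zeros((n, h2, w2, 4, c), dtype=DTYPE)
        np.put_along_axis(dwin, self._argmax[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dxc = dwin.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(
            n, 2 * h2, 2 * w2, c
        )
        if (2 * h2, 2 * w2) == (h, w):
            return dxc
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        dx[:, : 2 * h2, : 2 * w2, :] = dxc
        return dx


class Dropout:
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate, rng):
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def params(self):
        return []

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten:
    def params(self):
        return []

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense:
    def __init__(self, fan_in, units, rng, activation=None):
        self.activation = activation
        scale = np.sqrt(2.0 / fan_in) if activation == "relu" else np.sqrt(1.0 / fan_in)
        self.W = Param(rng.normal(0.0, scale, (fan_in, units)).astype(DTYPE))
        self.b = Param(np.zeros(units, dtype=DTYPE))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        z = x @ self.W.value + self.b.value
        self._x = x
        if self.activation == "relu":
            self._mask = z > 0
            return np.maximum(z, 0.0)
        self._mask = None
        return z

    def backward(self, dout):
        if self._mask is not None:
            dout = dout * self._mask
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        dx = dout @ self.W.value.T
        self._x = None
        return dx


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Network:
    """A realized model: either one Sequential or four branches + a head.

    ``forward`` returns logits (pre-softmax); ``predict_proba`` applies the
    softmax.
    """

    def __init__(self, spec: ModelSpec, trunk=None, branches=None, head=None):
        self.spec = spec
        self.trunk = trunk
        self.branches = branches
        self.head = head

    def params(self):
        out = []
        if self.trunk is not None:
            out.extend(self.trunk.params())
        else:
            for br in self.branches:
                out.extend(br.params())
            out.extend(self.head.params())
        return out

    def forward(self, x, train=False):
        if self.trunk is not None:
            return self.trunk.forward(x, train=train)
        feats = [br.forward(x, train=train) for br in self.branches]
        self._split = np.cumsum([f.shape[1] for f in feats])[:-1]
        return self.head.forward(np.concatenate(feats, axis=1), train=train)

    def backward(self, dlogits):
        if self.trunk is not None:
            return self.trunk.backward(dlogits)
        dconcat = self.head.backward(dlogits)
        for br, chunk in zip(self.branches, np.split(dconcat, self._split, axis=1)):
            br.backward(chunk)
        return None

    def predict_proba(self, x, batch_size: int = 64) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        outs = []
        for start in range(0, x.shape[0], batch_size):
            logits = self.forward(x[start : start + batch_size], train=False)
            outs.append(softmax(logits))
        return np.concatenate(outs, axis=0)

    # --- persistence ---------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p.value for i, p in enumerate(self.params())}

    def save(self, path) -> None:
        np.savez(path, **self.state_arrays())

    def load(self, path) -> None:
        with np.load(path) as data:
            for i, p in enumerate(self.params()):
                arr = data[f"param_{i}"]
                if arr.shape != p.value.shape:
                    raise ValueError(f"checkpoint mismatch on parameter {i}")
                p.value = arr.astype(DTYPE)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.mean(np.log(p[np.arange(n), y] + 1e-12)))
    grad = p
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(DTYPE)


def _realize_sequential(layers: list[LayerSpec], input_shape, rng) -> tuple[Sequential, tuple]:
    shape = tuple(input_shape)
    realized = []
    for layer in layers:
        if layer.kind == "input":
            continue
        if layer.kind == "conv":
            realized.append(Conv2D(layer.kernel, shape[2], layer.filters, rng, layer.activation))
            shape = (shape[0], shape[1], layer.filters)
        elif layer.kind == "maxpool":
            realized.append(MaxPool2D())
            shape = (shape[0] // 2, shape[1] // 2, shape[2])
        elif layer.kind == "dropout":
            realized.append(Dropout(layer.rate, rng))
        elif layer.kind == "flatten":
            realized.append(Flatten())
            shape = (int(np.prod(shape)),)
        elif layer.kind == "dense":
            realized.append(Dense(shape[0], layer.units, rng, layer.activation))
            shape = (layer.units,)
        elif layer.kind == "softmax":
            pass  # applied by the loss / predict_proba
        else:
            raise ValueError(f"cannot realize layer kind {layer.kind!r}")
    return Sequential(realized), shape


def realize(spec: ModelSpec, rng: np.random.Generator) -> Network:
    """Instantiate a ModelSpec with seeded weights."""
    from chirpnet.models import propagate_shapes

    propagate_shapes(spec)  # raises with the offending layer on bad extents
    if not spec.is_branched:
        trunk, _ = _realize_sequential(spec.layers, spec.input_shape, rng)
        return Network(spec, trunk=trunk)
    branches = []
    feat = 0
    for branch in spec.branches:
        seq, out = _realize_sequential(branch, spec.input_shape, rng)
        branches.append(seq)
        feat += out[0]
    head, _ = _realize_sequential(spec.head[1:] if spec.head[0].kind == "concat" else spec.head,
                                  (feat,), rng)
    return Network(spec, branches=branches, head=head)


class Adam:
    """Adam with the standard defaults (lr 1e-3, β1 0.9, β2 0.999, ε 1e-8)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
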