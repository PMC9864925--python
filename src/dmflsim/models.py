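"""Trainable classifier contract: parameters, loss, gradient, SGD, serialization.

The federated protocol only needs four things from a model: a flat parameter
vector it can ship between client and server, a probabilistic prediction, the
multi-class cross-entropy loss

    C_LOSS(W) = -(1/|D|) sum_{X in D} sum_{a=1..K} B_{X,a} log Q_{X,a}

(B one-hot true labels, Q predicted class probabilities), and the plain
gradient-descent update  W <- W - a * grad C_LOSS(W).  Everything here is
NumPy with hand-derived backward passes; gradient correctness is pinned
against central finite differences in the test suite.

Two real architectures ship behind a registry:

* ``linear`` — flattened-pixel softmax regression (also the toy gradient-check
  model at small input sizes);
* ``small-cnn`` — 2 conv(3x3) + ReLU + 2x2 max-pool stages, a 64-unit hidden
  dense layer and a softmax head (~2e4 parameters at 32x32).

``vgg16-sized`` / ``vgg19-sized`` / ``densenet169-sized`` reuse the small CNN
but pad the parameter vector to fixed larger dimensionalities; they exist so
communication accounting can reflect backbone size differences without
GPU-scale training.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._rng import child_rng
from .data import ImageSample, LabeledDataset

__all__ = [
    "ParameterVector",
    "GradientVector",
    "HyperParams",
    "ClassifierModel",
    "Architecture",
    "get_architecture",
    "register_architecture",
    "available_architectures",
    "predict_proba",
    "predict_labels",
    "accuracy",
    "cross_entropy_loss",
    "loss_gradient",
    "sgd_step",
    "serialize_parameters",
    "deserialize_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "model_size_bytes",
]

_EPS = 1e-12  # probability clip before log


@dataclass(frozen=True)
class ParameterVector:
    """Flat real-valued weight state of a classifier — the unit exchanged
    between client and server."""

    values: np.ndarray
    architecture_id: str

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError("parameter values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def dimensionality(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class GradientVector:
    """Gradient of the loss w.r.t. a matching :class:`ParameterVector`."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError("gradient values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def dimensionality(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class HyperParams:
    """Local-training hyperparameters: learning rate ``a``, batch size and
    epochs per round."""

    learning_rate: float = 0.1
    batch_size: int = 16
    epochs: int = 1

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs < 0:
            raise ValueError("learning_rate and batch_size must be positive, epochs >= 0")


class Architecture:
    """Forward/backward contract one architecture must satisfy."""

    architecture_id: str
    input_shape: tuple[int, int]
    num_classes: int
    dimensionality: int

    def init_params(self, seed: int) -> ParameterVector:
        raise NotImplementedError

    def logits(self, values: np.ndarray, X: np.ndarray) -> np.ndarray:
        """X: (n, H, W) -> logits (n, K)."""
        raise NotImplementedError

    def logits_and_backward(
        self, values: np.ndarray, X: np.ndarray
    ) -> tuple[np.ndarray, Callable[[np.ndarray], np.ndarray]]:
        """Return logits and a closure mapping d(loss)/d(logits) to the flat
        parameter gradient."""
        raise NotImplementedError


class LinearSoftmax(Architecture):
    """Softmax regression on flattened pixels: logits = X W + b."""

    def __init__(self, input_shape: tuple[int, int], num_classes: int):
        self.architecture_id = "linear"
        self.input_shape = tuple(input_shape)
        self.num_classes = int(num_classes)
        self._d_in = input_shape[0] * input_shape[1]
        self.dimensionality = self._d_in * num_classes + num_classes

    def init_params(self, seed: int) -> ParameterVector:
        rng = child_rng(seed, "init", self.architecture_id)
        w = rng.normal(0.0, 0.01, size=self._d_in * self.num_classes)
        b = np.zeros(self.num_classes)
        return ParameterVector(np.concatenate([w, b]), self.architecture_id)

    def _unpack(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cut = self._d_in * self.num_classes
        return values[:cut].reshape(self._d_in, self.num_classes), values[cut:]

    def logits(self, values: np.ndarray, X: np.ndarray) -> np.ndarray:
        W, b = self._unpack(values)
        return X.reshape(X.shape[0], -1) @ W + b

    def logits_and_backward(self, values, X):
        Xf = X.reshape(X.shape[0], -1)
        W, b = self._unpack(values)
        z = Xf @ W + b

        def backward(dz: np.ndarray) -> np.ndarray:
            dW = Xf.T @ dz
            db = dz.sum(axis=0)
            return np.concatenate([dW.ravel(), db])

        return z, backward


def _im2col(X: np.ndarray, kh: int, kw: int) -> np.ndarray:
    # X: (n, C, H, W) -> (n, oh, ow, C*kh*kw), stride 1, valid padding
    win = sliding_window_view(X, (kh, kw), axis=(2, 3))  # (n, C, oh, ow, kh, kw)
    n, C, oh, ow = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh, ow, C * kh * kw)


def _col2im(dcol: np.ndarray, x_shape: tuple, kh: int, kw: int) -> np.ndarray:
    n, C, H, W = x_shape
    oh, ow = H - kh + 1, W - kw + 1
    dcol = dcol.reshape(n, oh, ow, C, kh, kw)
    dX = np.zeros(x_shape)
    for i in range(kh):
        for j in range(kw):
            dX[:, :, i : i + oh, j : j + ow] += dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dX


class SmallCNN(Architecture):
    """Two 3x3 conv + ReLU + 2x2 max-pool stages, 64-unit dense, softmax head."""

    C1, C2, HIDDEN, KSIZE = 4, 8, 64, 3

    def __init__(self, input_shape: tuple[int, int], num_classes: int):
        self.architecture_id = "small-cnn"
        self.input_shape = tuple(input_shape)
        self.num_classes = int(num_classes)
        H, W = input_shape
        k = self.KSIZE
        h1, w1 = (H - k + 1) // 2, (W - k + 1) // 2
        h2, w2 = (h1 - k + 1) // 2, (w1 - k + 1) // 2
        if h2 < 1 or w2 < 1:
            raise ValueError(f"input {input_shape} too small for small-cnn")
        self._feat = self.C2 * h2 * w2
        self._shapes = [
            ("w1", (self.C1, 1, k, k)),
            ("b1", (self.C1,)),
            ("w2", (self.C2, self.C1, k, k)),
            ("b2", (self.C2,)),
            ("w3", (self._feat, self.HIDDEN)),
            ("b3", (self.HIDDEN,)),
            ("w4", (self.HIDDEN, self.num_classes)),
            ("b4", (self.num_classes,)),
        ]
        self.dimensionality = sum(int(np.prod(s)) for _, s in self._shapes)

    def init_params(self, seed: int) -> ParameterVector:
        rng = child_rng(seed, "init", self.architecture_id)
        parts = []
        for name, shape in self._shapes:
            if name.startswith("b"):
                parts.append(np.zeros(int(np.prod(shape))))
            else:
                fan_in = int(np.prod(shape[1:])) if len(shape) > 2 else shape[0]
                parts.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=int(np.prod(shape))))
        return ParameterVector(np.concatenate(parts), self.architecture_id)

    def _unpack(self, values: np.ndarray) -> dict[str, np.ndarray]:
        out, pos = {}, 0
        for name, shape in self._shapes:
            size = int(np.prod(shape))
            out[name] = values[pos : pos + size].reshape(shape)
            pos += size
        return out

    @staticmethod
    def _pool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # 2x2 max-pool, stride 2, odd trailing row/col dropped
        n, C, H, W = x.shape
        h, w = H // 2, W // 2
        xt = x[:, :, : 2 * h, : 2 * w].reshape(n, C, h, 2, w, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xt.reshape(n, C, h, w, 4)
        arg = flat.argmax(axis=-1)
        return np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0], arg

    @staticmethod
    def _pool_back(dy: np.ndarray, arg: np.ndarray, x_shape: tuple) -> np.ndarray:
        n, C, H, W = x_shape
        h, w = H // 2, W // 2
        dflat = np.zeros((n, C, h, w, 4))
        np.put_along_axis(dflat, arg[..., None], dy[..., None], axis=-1)
        dx = np.zeros(x_shape)
        dx[:, :, : 2 * h, : 2 * w] = (
            dflat.reshape(n, C, h, w, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, C, 2 * h, 2 * w)
        )
        return dx

    def _forward(self, values: np.ndarray, X: np.ndarray):
        p = self._unpack(values)
        k = self.KSIZE
        x0 = X[:, None, :, :]  # (n, 1, H, W)
        col1 = _im2col(x0, k, k)
        z1 = col1 @ p["w1"].reshape(self.C1, -1).T + p["b1"]  # (n, oh, ow, C1)
        a1 = np.maximum(z1, 0.0).transpose(0, 3, 1, 2)
        p1, arg1 = self._pool(a1)
        col2 = _im2col(p1, k, k)
        z2 = col2 @ p["w2"].reshape(self.C2, -1).T + p["b2"]
        a2 = np.maximum(z2, 0.0).transpose(0, 3, 1, 2)
        p2, arg2 = self._pool(a2)
        f = p2.reshape(X.shape[0], -1)
        z3 = f @ p["w3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        z4 = a3 @ p["w4"] + p["b4"]
        cache = (p, x0, col1, z1, a1, arg1, p1, col2, z2, a2, arg2, p2, f, z3, a3)
        return z4, cache

    def logits(self, values: np.ndarray, X: np.ndarray) -> np.ndarray:
        return self._forward(values, X)[0]

    def logits_and_backward(self, values, X):
        z4, cache = self._forward(values, X)
        (p, x0, col1, z1, a1, arg1, p1, col2, z2, a2, arg2, p2, f, z3, a3) = cache
        k = self.KSIZE

        def backward(dz4: np.ndarray) -> np.ndarray:
            dw4 = a3.T @ dz4
            db4 = dz4.sum(axis=0)
            da3 = dz4 @ p["w4"].T
            dz3 = da3 * (z3 > 0)
            dw3 = f.T @ dz3
            db3 = dz3.sum(axis=0)
            df = dz3 @ p["w3"].T
            dp2 = df.reshape(p2.shape)
            da2 = self._pool_back(dp2, arg2, a2.shape)
            dz2 = da2.transpose(0, 2, 3, 1) * (z2 > 0)  # (n, oh, ow, C2)
            dw2 = np.tensordot(dz2, col2, axes=([0, 1, 2], [0, 1, 2])).reshape(p["w2"].shape)
            db2 = dz2.sum(axis=(0, 1, 2))
            dcol2 = dz2 @ p["w2"].reshape(self.C2, -1)
            dp1 = _col2im(dcol2, p1.shape, k, k)
            da1 = self._pool_back(dp1, arg1, a1.shape)
            dz1 = da1.transpose(0, 2, 3, 1) * (z1 > 0)
            dw1 = np.tensordot(dz1, col1, axes=([0, 1, 2], [0, 1, 2])).reshape(p["w1"].shape)
            db1 = dz1.sum(axis=(0, 1, 2))
            return np.concatenate(
                [dw1.ravel(), db1, dw2.ravel(), db2, dw3.ravel(), db3, dw4.ravel(), db4]
            )

        return z4, backward


class PaddedArchitecture(Architecture):
    """Wrap a base architecture, padding the parameter vector to a fixed
    larger dimensionality.  The padding entries are inert (zero gradient);
    they exist solely so upload-size accounting reflects a bigger backbone."""

    def __init__(self, base: Architecture, architecture_id: str, dimensionality: int):
        if dimensionality < base.dimensionality:
            raise ValueError(
                f"padded dimensionality {dimensionality} is below the base "
                f"architecture's {base.dimensionality}"
            )
        self._base = base
        self.architecture_id = architecture_id
        self.input_shape = base.input_shape
        self.num_classes = base.num_classes
        self.dimensionality = int(dimensionality)

    def init_params(self, seed: int) -> ParameterVector:
        core = self._base.init_params(seed).values
        pad = np.zeros(self.dimensionality - core.size)
        return ParameterVector(np.concatenate([core, pad]), self.architecture_id)

    def logits(self, values, X):
        return self._base.logits(values[: self._base.dimensionality], X)

    def logits_and_backward(self, values, X):
        z, back = self._base.logits_and_backward(values[: self._base.dimensionality], X)

        def backward(dz):
            g = back(dz)
            return np.concatenate([g, np.zeros(self.dimensionality - g.size)])

        return z, backward


# registry: id -> factory(input_shape, num_classes) -> Architecture
_REGISTRY: dict[str, Callable[[tuple[int, int], int], Architecture]] = {}


def register_architecture(architecture_id: str, factory) -> None:
    _REGISTRY[architecture_id] = factory


def available_architectures() -> list[str]:
    return sorted(_REGISTRY)


register_architecture("linear", LinearSoftmax)
register_architecture("small-cnn", SmallCNN)
# padded dimensionalities at ~1:1000 of backbone scale, ordered per the sizes
# the communication experiments assume (vgg16 smallest, densenet169 largest)
for _aid, _dim in (("vgg16-sized", 138_000), ("vgg19-sized", 144_000), ("densenet169-sized", 172_000)):
    register_architecture(
        _aid,
        lambda shape, K, _aid=_aid, _dim=_dim: PaddedArchitecture(SmallCNN(shape, K), _aid, _dim),
    )


def get_architecture(
    architecture_id: str, input_shape: tuple[int, int], num_classes: int
) -> Architecture:
    try:
        factory = _REGISTRY[architecture_id]
    except KeyError:
        raise KeyError(
            f"unknown architecture {architecture_id!r}; available: {available_architectures()}"
        ) from None
    return factory(tuple(input_shape), int(num_classes))


@dataclass
class ClassifierModel:
    """An architecture bound to a concrete parameter vector."""

    architecture: Architecture
    parameters: ParameterVector

    def __post_init__(self) -> None:
        if self.parameters.architecture_id != self.architecture.architecture_id:
            raise ValueError("parameter vector belongs to a different architecture")
        if self.parameters.dimensionality != self.architecture.dimensionality:
            raise ValueError(
                f"parameter dimensionality {self.parameters.dimensionality} != "
                f"architecture dimensionality {self.architecture.dimensionality}"
            )

    @classmethod
    def initialize(
        cls,
        architecture_id: str,
        input_shape: tuple[int, int],
        num_classes: int,
        seed: int = 0,
    ) -> "ClassifierModel":
        arch = get_architecture(architecture_id, input_shape, num_classes)
        return cls(arch, arch.init_params(seed))

    def with_parameters(self, params: ParameterVector) -> "ClassifierModel":
        return ClassifierModel(self.architecture, params)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _check_images(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 2:
        X = X[None]
    if X.shape[1:] != tuple(model.architecture.input_shape):
        raise ValueError(
            f"image shape {X.shape[1:]} does not match model input "
            f"{model.architecture.input_shape}"
        )
    return X


def predict_proba(model: ClassifierModel, image: ImageSample | np.ndarray) -> np.ndarray:
    """Length-K probability vector for one image (nonnegative, sums to 1)."""
    px = image.pixels if isinstance(image, ImageSample) else image
    X = _check_images(model, px)
    return _softmax(model.architecture.logits(model.parameters.values, X))[0]


def predict_labels(model: ClassifierModel, data: LabeledDataset) -> np.ndarray:
    """Arg-max class prediction for every sample of a dataset."""
    X = _check_images(model, data.pixels_array())
    return model.architecture.logits(model.parameters.values, X).argmax(axis=1)


def accuracy(model: ClassifierModel, data: LabeledDataset) -> float:
    if len(data) == 0:
        raise ValueError("cannot evaluate accuracy on an empty dataset")
    return float(np.mean(predict_labels(model, data) == data.labels_array()))


def cross_entropy_loss(model: ClassifierModel, data: LabeledDataset) -> float:
    """Mean over samples of -log(probability assigned to the true class)."""
    if len(data) == 0:
        raise ValueError("cross-entropy loss of an empty dataset is undefined")
    X = _check_images(model, data.pixels_array())
    probs = _softmax(model.architecture.logits(model.parameters.values, X))
    p_true = probs[np.arange(len(data)), data.labels_array()]
    return float(-np.mean(np.log(np.clip(p_true, _EPS, 1.0))))


def loss_gradient(model: ClassifierModel, batch: LabeledDataset) -> GradientVector:
    """Analytic gradient of :func:`cross_entropy_loss` w.r.t. every parameter."""
    if len(batch) == 0:
        raise ValueError("gradient of an empty batch is undefined")
    X = _check_images(model, batch.pixels_array())
    y = batch.labels_array()
    z, backward = model.architecture.logits_and_backward(model.parameters.values, X)
    probs = _softmax(z)
    dz = probs.copy()
    dz[np.arange(len(batch)), y] -= 1.0
    dz /= len(batch)
    return GradientVector(backward(dz))


def sgd_step(
    params: ParameterVector, gradient: GradientVector, learning_rate: float
) -> ParameterVector:
    """One plain gradient-descent update  W <- W - a * g."""
    if learning_rate <= 0:
        raise ValueError("learning rate must be positive")
    if gradient.dimensionality != params.dimensionality:
        raise ValueError(
            f"gradient dimensionality {gradient.dimensionality} != "
            f"parameter dimensionality {params.dimensionality}"
        )
    return ParameterVector(params.values - learning_rate * gradient.values, params.architecture_id)


# ---------------------------------------------------------------------------
# Serialization: little-endian binary with magic, architecture id, dimension,
# float64 payload and a CRC32 trailer.  Byte length = 14 + len(arch id) + 8 d.

_MAGIC = b"DMFLPV1\x00"


def serialize_parameters(params: ParameterVector) -> bytes:
    aid = params.architecture_id.encode("utf-8")
    payload = params.values.astype("<f8").tobytes()
    body = _MAGIC + struct.pack("<H", len(aid)) + aid + struct.pack("<I", params.dimensionality) + payload
    return body + struct.pack("<I", zlib.crc32(body))


def deserialize_parameters(blob: bytes) -> ParameterVector:
    if len(blob) < len(_MAGIC) + 10 or blob[: len(_MAGIC)] != _MAGIC:
        raise ValueError("not a parameter-vector payload (bad magic)")
    body, (crc,) = blob[:-4], struct.unpack("<I", blob[-4:])
    if zlib.crc32(body) != crc:
        raise ValueError("corrupted parameter payload (checksum mismatch)")
    pos = len(_MAGIC)
    (alen,) = struct.unpack_from("<H", body, pos)
    pos += 2
    aid = body[pos : pos + alen].decode("utf-8")
    pos += alen
    (d,) = struct.unpack_from("<I", body, pos)
    pos += 4
    values = np.frombuffer(body, dtype="<f8", count=d, offset=pos)
    if values.size != d or pos + 8 * d != len(body):
        raise ValueError("corrupted parameter payload (length mismatch)")
    return ParameterVector(values.copy(), aid)


def save_checkpoint(params: ParameterVector, path) -> None:
    with open(path, "wb") as fh:
        fh.write(serialize_parameters(params))


def load_checkpoint(path) -> ParameterVector:
    with open(path, "rb") as fh:
        return deserialize_parameters(fh.read())


def model_size_bytes(model: ClassifierModel | ParameterVector) -> int:
    """Upload size of a model's parameters — drives simulated transfer time."""
    params = model.parameters if isinstance(model, ClassifierModel) else model
    return len(serialize_parameters(params))
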