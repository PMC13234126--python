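"""Tiny reference segmentation backbone: numpy 3-D convs with explicit gradients.

The two-stage engine is backbone-agnostic; any object satisfying the
:class:`SegmentationModel` contract (``n_in_channels``, ``n_classes``,
``predict`` returning voxel-wise class probabilities) plugs in.  This module
ships a deliberately small reference network (< 100k parameters) so the full
pipeline trains and runs on one CPU core in seconds: a 3x3x3 convolution
block followed by 1x1x1 blocks with ReLU nonlinearities, trained by
fixed-step gradient descent under a polynomial learning-rate decay
(power 0.9).

Positional features.  The reference network internally appends seven channels
to its input — the voxel coordinates of the patch, centred and scaled to
[-1, 1] over the whole volume, the radial distance from the volume centre,
and the unit direction vector from the centre (a spherical positional
encoding).  Large-patch networks see most of a brain per window and recover
global position from anatomy; at desk scale a small receptive field cannot
tell the two hemispheres of a symmetric phantom apart without position, so
the engine passes each patch's origin to the model.  The declared
``n_in_channels`` counts only data channels (4 coarse / 5 fine); the
positional channels are an internal detail of this backbone.

Convolutions are evaluated by im2col + one GEMM; gradients are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SegmentationModel", "TinyConvNet", "softmax"]


class SegmentationModel:
    """Duck-typed contract for pluggable backbones.

    Required: ``n_in_channels``, ``n_classes`` attributes and
    ``predict(patch, origin=..., volume_shape=...)`` returning an array of
    shape ``(n_classes,) + patch_spatial_shape`` of non-negative scores
    summing to 1 per voxel.  Trainable models additionally expose
    ``forward_logits`` / ``backward`` / ``step`` (see :class:`TinyConvNet`).
    """

    n_in_channels: int
    n_classes: int

    def predict(self, patch, origin=(0, 0, 0), volume_shape=None):  # pragma: no cover
        raise NotImplementedError


def softmax(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(C, X, Y, Z) -> (X*Y*Z, C*27) columns of the 3x3x3 neighbourhood."""
    c, nx, ny, nz = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    cols = np.empty((c, 27, nx, ny, nz), dtype=x.dtype)
    k = 0
    for dx in range(3):
        for dy in range(3):
            for dz in range(3):
                cols[:, k] = xp[:, dx : dx + nx, dy : dy + ny, dz : dz + nz]
                k += 1
    return cols.reshape(c * 27, -1).T


def _col2im3(dcols: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Adjoint of :func:`_im2col3`; accumulates into the input gradient."""
    c, nx, ny, nz = shape
    d = dcols.T.reshape(c, 27, nx, ny, nz)
    gp = np.zeros((c, nx + 2, ny + 2, nz + 2), dtype=dcols.dtype)
    k = 0
    for dx in range(3):
        for dy in range(3):
            for dz in range(3):
                gp[:, dx : dx + nx, dy : dy + ny, dz : dz + nz] += d[:, k]
                k += 1
    return gp[:, 1:-1, 1:-1, 1:-1]


@dataclass
class _ConvLayer:
    """'Same'-padded 3-D convolution, kernel 1 or 3, with ReLU option."""

    weight: np.ndarray  # (C_out, C_in * k^3)
    bias: np.ndarray  # (C_out,)
    kernel: int
    relu: bool
    _cache: tuple | None = field(default=None, repr=False)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        c_in = x.shape[0]
        spatial = x.shape[1:]
        if self.kernel == 1:
            cols = x.reshape(c_in, -1).T
        else:
            cols = _im2col3(x)
        out = cols @ self.weight.T + self.bias
        out = out.T.reshape((self.weight.shape[0],) + spatial)
        if self.relu:
            pre = out
            out = np.maximum(out, 0.0)
            if train:
                self._cache = (cols, x.shape, pre > 0)
        elif train:
            self._cache = (cols, x.shape, None)
        return out

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        cols, in_shape, relu_mask = self._cache
        if relu_mask is not None:
            dout = dout * relu_mask
        dflat = dout.reshape(dout.shape[0], -1).T  # (V, C_out)
        dw = dflat.T @ cols
        db = dflat.sum(axis=0)
        dcols = dflat @ self.weight
        if self.kernel == 1:
            dx = dcols.T.reshape(in_shape)
        else:
            dx = _col2im3(dcols, in_shape)
        self._cache = None
        return dx, dw, db


class TinyConvNet(SegmentationModel):
    """Reference backbone: conv3(ReLU) -> conv1(ReLU) -> conv1 -> softmax.

    Parameters
    ----------
    n_in_channels
        Number of data channels the model consumes (4 for the coarse stage,
        5 for the fine stages).
    n_classes
        Output classes including background.
    hidden
        Widths of the two hidden blocks.
    use_coords
        Append the internal positional channels (see module docstring).
    seed
        Initialisation seed (He-style init).
    """

    N_COORD = 7  # x, y, z in [-1, 1]; radial distance; unit direction vector

    def __init__(
        self,
        n_in_channels: int,
        n_classes: int,
        hidden: tuple[int, int] = (24, 48),
        first_kernel: int = 3,
        use_coords: bool = True,
        seed: int = 0,
        channel_names: tuple[str, ...] | None = None,
    ) -> None:
        if channel_names is not None and len(channel_names) != n_in_channels:
            raise ValueError("channel_names length must equal n_in_channels")
        if first_kernel not in (1, 3):
            raise ValueError("first_kernel must be 1 or 3")
        self.n_in_channels = int(n_in_channels)
        self.n_classes = int(n_classes)
        self.use_coords = bool(use_coords)
        self.first_kernel = int(first_kernel)
        self.channel_names = tuple(channel_names) if channel_names else None
        self.channel_stats: tuple[np.ndarray, np.ndarray] | None = None
        rng = np.random.default_rng(seed)
        c0 = self.n_in_channels + (self.N_COORD if use_coords else 0)
        h1, h2 = hidden
        self.layers = [
            self._make_layer(rng, c0, h1, kernel=first_kernel, relu=True),
            self._make_layer(rng, h1, h2, kernel=1, relu=True),
            self._make_layer(rng, h2, self.n_classes, kernel=1, relu=False),
        ]

    @staticmethod
    def _make_layer(rng, c_in: int, c_out: int, kernel: int, relu: bool) -> _ConvLayer:
        fan_in = c_in * kernel ** 3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in)).astype(np.float32)
        return _ConvLayer(w, np.zeros(c_out, dtype=np.float32), kernel, relu)

    @property
    def n_parameters(self) -> int:
        return sum(l.weight.size + l.bias.size for l in self.layers)

    # -- positional features ------------------------------------------------

    def _coord_features(self, spatial, origin, volume_shape) -> np.ndarray:
        if volume_shape is None:
            volume_shape = spatial
        feats = np.empty((self.N_COORD,) + tuple(spatial), dtype=np.float32)
        axes = []
        for a, (sz, o, vs) in enumerate(zip(spatial, origin, volume_shape)):
            half = (vs - 1) / 2.0
            scale = half if half > 0 else 1.0
            coords = ((np.arange(o, o + sz) - half) / scale).astype(np.float32)
            shape = [1, 1, 1]
            shape[a] = sz
            axes.append(coords.reshape(shape))
        feats[0] = np.broadcast_to(axes[0], spatial)
        feats[1] = np.broadcast_to(axes[1], spatial)
        feats[2] = np.broadcast_to(axes[2], spatial)
        norm = np.sqrt(feats[0] ** 2 + feats[1] ** 2 + feats[2] ** 2)
        feats[3] = norm / np.sqrt(3.0)
        # unit direction from the volume centre (spherical encoding): any
        # angular-sector or slab boundary through the centre is linear in it
        safe = np.maximum(norm, np.float32(1e-6))
        feats[4] = feats[0] / safe
        feats[5] = feats[1] / safe
        feats[6] = feats[2] / safe
        return feats

    def _with_coords(self, patch, origin, volume_shape) -> np.ndarray:
        if patch.shape[0] != self.n_in_channels:
            raise ValueError(
                f"expected {self.n_in_channels} channels, got {patch.shape[0]}"
            )
        if not self.use_coords:
            return patch
        coords = self._coord_features(patch.shape[1:], origin, volume_shape)
        return np.concatenate([patch, coords], axis=0)

    # -- inference / training ----------------------------------------------

    def forward_logits(
        self, patch, origin=(0, 0, 0), volume_shape=None, train: bool = False
    ) -> np.ndarray:
        x = self._with_coords(np.asarray(patch, dtype=np.float32), origin, volume_shape)
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def predict(self, patch, origin=(0, 0, 0), volume_shape=None) -> np.ndarray:
        return softmax(self.forward_logits(patch, origin, volume_shape), axis=0)

    def backward(self, dlogits: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        """Backprop a gradient w.r.t. the output logits; returns per-layer grads."""
        grads: list[tuple[np.ndarray, np.ndarray]] = []
        d = dlogits
        for layer in reversed(self.layers):
            d, dw, db = layer.backward(d)
            grads.append((dw, db))
        grads.reverse()
        return grads

    def step(self, grads, lr: float) -> None:
        for layer, (dw, db) in zip(self.layers, grads):
            layer.weight -= lr * dw
            layer.bias -= lr * db

    def accumulate(self, total, grads):
        if total is None:
            return [(dw.copy(), db.copy()) for dw, db in grads]
        return [(tw + dw, tb + db) for (tw, tb), (dw, db) in zip(total, grads)]

    # -- (de)serialisation --------------------------------------------------

    def state_dict(self) -> dict:
        state = {
            "n_in_channels": self.n_in_channels,
            "n_classes": self.n_classes,
            "use_coords": self.use_coords,
            "first_kernel": self.first_kernel,
            "hidden": tuple(l.bias.size for l in self.layers[:-1]),
            "channel_names": self.channel_names,
        }
        for i, l in enumerate(self.layers):
            state[f"w{i}"] = l.weight.copy()
            state[f"b{i}"] = l.bias.copy()
            state[f"k{i}"] = l.kernel
        if self.channel_stats is not None:
            state["stats_mean"], state["stats_std"] = self.channel_stats
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, l in enumerate(self.layers):
            l.weight = np.asarray(state[f"w{i}"], dtype=np.float32)
            l.bias = np.asarray(state[f"b{i}"], dtype=np.float32)
        if "stats_mean" in state:
            self.channel_stats = (
                np.asarray(state["stats_mean"]),
                np.asarray(state["stats_std"]),
            )


class ConstantModel(SegmentationModel):
    """Outputs a fixed score vector everywhere; handy for contract tests."""

    def __init__(self, scores) -> None:
        scores = np.asarray(scores, dtype=float)
        self.scores = scores / scores.sum()
        self.n_classes = len(scores)
        self.n_in_channels = 1

    def predict(self, patch, origin=(0, 0, 0), volume_shape=None) -> np.ndarray:
        spatial = patch.shape[1:]
        out = np.empty((self.n_classes,) + spatial)
        out[:] = self.scores.reshape((-1,) + (1,) * len(spatial))
        return out
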