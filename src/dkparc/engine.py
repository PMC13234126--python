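"""Backbone-agnostic two-stage training and sliding-window inference.

Stage one segments the four-channel map set (default channel order T, F, CS,
E1) into the seven coarse groups plus background.  Stage two trains one
model per non-terminal group on a five-channel input: the four maps plus the
coarse mask scaled to [0, 1] (:func:`dkparc.hierarchy.group_channel`).  The
stages are trained sequentially, not jointly.

Training minimises an equally weighted (1:1) composite of soft Dice loss and
cross-entropy; a control variant swaps the cross-entropy term for a
class-weighted one with inverse-label-frequency weights.  Inference tiles
the volume with 0.5-overlap sliding windows blended under a separable
Gaussian weight.

The published training scale (patch 128^3, batch 2, 250k iterations on GPU)
is recorded in the ``PAPER_*`` constants; desk-scale defaults are small so a
phantom pipeline trains in seconds on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .backbone import SegmentationModel, TinyConvNet, softmax
from .dti import ScalarMapSet
from .grids import LabelVolume, Namespace
from .hierarchy import (
    LabelHierarchy,
    LabelStats,
    group_channel,
    inverse_frequency_weights,
    to_coarse,
)

__all__ = [
    "TrainConfig",
    "InferenceConfig",
    "dice_ce_loss",
    "sample_patches",
    "train_stage",
    "sliding_window_predict",
    "run_coarse",
    "run_fine",
    "normalize_channels",
    "train_two_stage",
    "predict_two_stage",
    "PAPER_PATCH_SIZE",
    "PAPER_BATCH_SIZE",
]

PAPER_PATCH_SIZE = 128
PAPER_BATCH_SIZE = 2

DICE_EPS = 1e-5


@dataclass
class TrainConfig:
    patch_size: int = 24
    batch_size: int = 2
    iterations: int = 400
    loss: str = "dice_ce"  # or "dice_wce"
    class_weights: np.ndarray | None = None
    learning_rate: float = 0.01
    momentum: float = 0.99  # sgd only
    optimizer: str = "adam"  # or "sgd" (fixed step + Nesterov momentum)
    lr_decay_power: float = 0.9
    foreground_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss not in ("dice_ce", "dice_wce"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class InferenceConfig:
    patch_size: int = 24
    overlap_fraction: float = 0.5
    gaussian_sigma_scale: float = 1.0 / 8.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1)")
        step = max(1, int(round(self.patch_size * (1.0 - self.overlap_fraction))))
        self.step = step


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def dice_ce_loss(
    scores: np.ndarray,
    target: np.ndarray,
    class_weights: np.ndarray | None = None,
    return_grad: bool = False,
):
    """Soft Dice plus (optionally class-weighted) cross-entropy, 1:1.

    ``scores`` holds voxel-wise class probabilities, shape ``(C,) + spatial``;
    ``target`` integer labels ``< C``.  The Dice term averages
    ``2*sum(p*y) / (sum(p) + sum(y) + eps)`` over the foreground classes of
    this sample (background excluded); the cross-entropy term is the mean
    over voxels of ``-w[y] * ln p_y``.  With ``return_grad`` the gradient
    with respect to the pre-softmax logits is returned as well.
    """
    scores = np.asarray(scores, dtype=float)
    target = np.asarray(target)
    n_classes = scores.shape[0]
    if scores.shape[1:] != target.shape:
        raise ValueError(
            f"scores spatial shape {scores.shape[1:]} != target shape {target.shape}"
        )
    if target.max(initial=0) >= n_classes:
        raise ValueError("target labels must be < n_classes")

    p_flat = scores.reshape(n_classes, -1)
    t_flat = target.reshape(-1)
    n_vox = t_flat.size
    onehot = np.zeros_like(p_flat)
    onehot[t_flat, np.arange(n_vox)] = 1.0

    # cross-entropy
    w = np.ones(n_classes) if class_weights is None else np.asarray(class_weights, float)
    if w.shape != (n_classes,):
        raise ValueError("class_weights length must equal n_classes")
    p_true = np.clip(p_flat[t_flat, np.arange(n_vox)], 1e-12, None)
    w_vox = w[t_flat]
    ce = float(np.mean(w_vox * -np.log(p_true)))

    # soft Dice over foreground classes
    fg = np.arange(1, n_classes)
    inter = (p_flat[fg] * onehot[fg]).sum(axis=1)
    denom = p_flat[fg].sum(axis=1) + onehot[fg].sum(axis=1) + DICE_EPS
    dice = 2.0 * inter / denom
    dice_loss = float(1.0 - dice.mean()) if len(fg) else 0.0

    loss = dice_loss + ce
    if not return_grad:
        return loss

    # gradient w.r.t. logits: CE part is w[y]*(p - y)/N directly
    dz = (w_vox[None, :] * (p_flat - onehot)) / n_vox
    # Dice part: d/dp then chain through softmax
    if len(fg):
        g = np.zeros_like(p_flat)
        coef = -1.0 / len(fg)
        g[fg] = coef * (2.0 * onehot[fg] * denom[:, None] - 2.0 * inter[:, None]) / (
            denom[:, None] ** 2
        )
        dz += p_flat * (g - (p_flat * g).sum(axis=0, keepdims=True))
    return loss, dz.reshape(scores.shape)


# ---------------------------------------------------------------------------
# normalisation and patch sampling
# ---------------------------------------------------------------------------


def normalize_channels(
    stack: np.ndarray,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
    skip_channels: tuple[int, ...] = (),
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Per-channel z-score over foreground voxels (any channel non-zero).

    ``skip_channels`` (e.g. the [0, 1] coarse-mask channel) pass through
    unchanged.  Returns the normalised stack and the (mean, std) stats so a
    trained model can replay them at inference time.
    """
    stack = np.asarray(stack, dtype=float)
    c = stack.shape[0]
    if stats is None:
        fg = np.any(stack != 0, axis=0)
        if not fg.any():
            fg = np.ones(stack.shape[1:], dtype=bool)
        mean = np.zeros(c)
        std = np.ones(c)
        for i in range(c):
            if i in skip_channels:
                continue
            vals = stack[i][fg]
            mean[i] = vals.mean()
            s = vals.std()
            std[i] = s if s > 1e-12 else 1.0
        stats = (mean, std)
    mean, std = stats
    out = (stack - mean.reshape(-1, 1, 1, 1)) / std.reshape(-1, 1, 1, 1)
    return out, stats


def _extract_patch(arr: np.ndarray, origin, size: int) -> np.ndarray:
    """Crop with zero padding; works for (X,Y,Z) and (C,X,Y,Z) arrays."""
    spatial_ndim = 3
    lead = arr.ndim - spatial_ndim
    shape = arr.shape[lead:]
    out_shape = arr.shape[:lead] + (size,) * 3
    out = np.zeros(out_shape, dtype=arr.dtype)
    src, dst = [slice(None)] * lead, [slice(None)] * lead
    for o, s in zip(origin, shape):
        lo, hi = max(o, 0), min(o + size, s)
        if lo >= hi:
            return out
        src.append(slice(lo, hi))
        dst.append(slice(lo - o, hi - o))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _draw_origin(labels, fg_coords, patch: int, fg_fraction: float, rng) -> tuple:
    shape = labels.shape
    if fg_coords is not None and len(fg_coords) and rng.random() < fg_fraction:
        center = fg_coords[rng.integers(len(fg_coords))]
        origin = [int(c) - patch // 2 for c in center]
    else:
        origin = [int(rng.integers(-(patch // 4), s - patch + patch // 4 + 1))
                  if s > patch else 0 for s in shape]
    return tuple(
        int(np.clip(o, -(patch // 2), max(s - patch // 2, 0)))
        for o, s in zip(origin, shape)
    )


def sample_patches(
    channels: np.ndarray,
    labels: np.ndarray,
    patch_size: int,
    rng: np.random.Generator,
    foreground_fraction: float = 0.5,
) -> Iterator[tuple[np.ndarray, np.ndarray, tuple[int, int, int]]]:
    """Endless stream of (channel patch, label patch, origin).

    At least ``foreground_fraction`` of draws are centred on a foreground
    voxel (oversampling against background dominance); the rest are uniform.
    Edge patches are zero-padded.  Deterministic under the supplied rng.
    """
    fg = np.argwhere(labels > 0)
    fg_coords = fg if len(fg) else None
    while True:
        origin = _draw_origin(labels, fg_coords, patch_size, foreground_fraction, rng)
        yield (
            _extract_patch(channels, origin, patch_size),
            _extract_patch(labels, origin, patch_size),
            origin,
        )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train_stage(
    model: TinyConvNet,
    volumes: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
) -> tuple[TinyConvNet, list[float]]:
    """Train one stage by fixed-step gradient descent with polynomial decay.

    ``volumes`` is a list of (channel stack (C,X,Y,Z), label lattice) pairs
    already normalised; labels are model-space class indices.  Returns the
    model and the per-iteration mean batch loss.  ``iterations == 0`` returns
    the model untouched with an empty trace.
    """
    if not volumes:
        raise ValueError("no training volumes")
    c = volumes[0][0].shape[0]
    if c != model.n_in_channels:
        raise ValueError(f"expected {model.n_in_channels} channels, got {c}")
    if config.iterations == 0:
        return model, []

    weights = None
    if config.loss == "dice_wce":
        weights = config.class_weights
        if weights is None:
            stats = LabelStats()
            for _, lab in volumes:
                ids, cnt = np.unique(lab, return_counts=True)
                for i, n in zip(ids.tolist(), cnt.tolist()):
                    stats.counts[i] = stats.counts.get(i, 0) + n
            weights = inverse_frequency_weights(stats, model.n_classes)

    rng = np.random.default_rng(config.seed)
    velocity = None
    adam_m = adam_v = None
    samplers = [
        sample_patches(ch, lab, config.patch_size, rng, config.foreground_fraction)
        for ch, lab in volumes
    ]
    vol_shapes = [lab.shape for _, lab in volumes]

    trace: list[float] = []
    lr0, power, t_max = config.learning_rate, config.lr_decay_power, config.iterations
    for it in range(config.iterations):
        lr = lr0 * (1.0 - it / t_max) ** power
        batch_loss = 0.0
        total = None
        for _ in range(config.batch_size):
            v = int(rng.integers(len(samplers)))
            patch, lab_patch, origin = next(samplers[v])
            logits = model.forward_logits(
                patch, origin=origin, volume_shape=vol_shapes[v], train=True
            )
            loss, dz = dice_ce_loss(
                softmax(logits), lab_patch, class_weights=weights, return_grad=True
            )
            batch_loss += loss
            total = model.accumulate(total, model.backward(dz.astype(np.float32)))
        mean_grads = [(dw / config.batch_size, db / config.batch_size)
                      for dw, db in total]
        if config.optimizer == "adam":
            b1, b2, eps = 0.9, 0.999, 1e-8
            if adam_m is None:
                adam_m = [(np.zeros_like(dw), np.zeros_like(db))
                          for dw, db in mean_grads]
                adam_v = [(np.zeros_like(dw), np.zeros_like(db))
                          for dw, db in mean_grads]
            t = it + 1
            stepped = []
            for k, (dw, db) in enumerate(mean_grads):
                mw, mb = adam_m[k]
                vw, vb = adam_v[k]
                mw = b1 * mw + (1 - b1) * dw
                mb = b1 * mb + (1 - b1) * db
                vw = b2 * vw + (1 - b2) * dw * dw
                vb = b2 * vb + (1 - b2) * db * db
                adam_m[k] = (mw, mb)
                adam_v[k] = (vw, vb)
                c1, c2 = 1 - b1 ** t, 1 - b2 ** t
                stepped.append((
                    (mw / c1) / (np.sqrt(vw / c2) + eps),
                    (mb / c1) / (np.sqrt(vb / c2) + eps),
                ))
            mean_grads = stepped
        elif config.momentum > 0:  # Nesterov-style velocity update
            if velocity is None:
                velocity = [(np.zeros_like(dw), np.zeros_like(db))
                            for dw, db in mean_grads]
            mu = config.momentum
            velocity = [(mu * vw + dw, mu * vb + db)
                        for (vw, vb), (dw, db) in zip(velocity, mean_grads)]
            mean_grads = [(dw + mu * vw, db + mu * vb)
                          for (vw, vb), (dw, db) in zip(velocity, mean_grads)]
        model.step(mean_grads, lr)
        trace.append(batch_loss / config.batch_size)
    return model, trace


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def _window_starts(size: int, patch: int, step: int) -> list[int]:
    if size <= patch:
        return [0]
    starts = list(range(0, size - patch + 1, step))
    if starts[-1] != size - patch:
        starts.append(size - patch)
    return starts


def _gaussian_weight(patch: int, sigma_scale: float) -> np.ndarray:
    sigma = max(sigma_scale * patch, 1e-3)
    x = np.arange(patch) - (patch - 1) / 2.0
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g = np.maximum(g, g.max() * 1e-4)
    return g[:, None, None] * g[None, :, None] * g[None, None, :]


def sliding_window_predict(
    model: SegmentationModel,
    channels: np.ndarray,
    config: InferenceConfig,
) -> np.ndarray:
    """Tile the volume with overlapping windows and blend with Gaussian weights.

    Per-window class scores are accumulated under a separable Gaussian
    centred in the window; accumulated scores are renormalised to a voxel-wise
    probability simplex and cropped back to the input extent.  Volumes smaller
    than the patch are zero-padded to a single window.
    """
    channels = np.asarray(channels, dtype=float)
    vol_shape = channels.shape[1:]
    p = config.patch_size
    padded = tuple(max(s, p) for s in vol_shape)
    if padded != vol_shape:
        pad = [(0, 0)] + [(0, ps - s) for ps, s in zip(padded, vol_shape)]
        work = np.pad(channels, pad)
    else:
        work = channels

    weight = _gaussian_weight(p, config.gaussian_sigma_scale)
    num = np.zeros((model.n_classes,) + padded)
    den = np.zeros(padded)
    for ox in _window_starts(padded[0], p, config.step):
        for oy in _window_starts(padded[1], p, config.step):
            for oz in _window_starts(padded[2], p, config.step):
                patch = work[:, ox : ox + p, oy : oy + p, oz : oz + p]
                scores = model.predict(
                    patch, origin=(ox, oy, oz), volume_shape=vol_shape
                )
                sl = (slice(ox, ox + p), slice(oy, oy + p), slice(oz, oz + p))
                num[(slice(None),) + sl] += scores * weight
                den[sl] += weight
    out = num / np.maximum(den, 1e-12)
    out /= np.maximum(out.sum(axis=0, keepdims=True), 1e-12)
    return out[:, : vol_shape[0], : vol_shape[1], : vol_shape[2]]


def _check_channel_order(model, names) -> None:
    if getattr(model, "channel_names", None) and names is not None:
        if tuple(model.channel_names) != tuple(names):
            raise ValueError(
                f"channel order mismatch: model trained on {model.channel_names}, "
                f"got {tuple(names)}"
            )


def run_coarse(
    maps: ScalarMapSet,
    model: SegmentationModel,
    config: InferenceConfig | None = None,
) -> tuple[LabelVolume, np.ndarray]:
    """Stage-one prediction: argmax over background + coarse-group scores.

    Returns the coarse label volume and the raw score volume (for the
    softmax-derived confidence analysis).  Ties break toward the lower class
    id (first maximum).
    """
    config = config or InferenceConfig()
    _check_channel_order(model, maps.names)
    stack, _ = normalize_channels(maps.stack(), stats=getattr(model, "channel_stats", None))
    scores = sliding_window_predict(model, stack, config)
    labels = scores.argmax(axis=0).astype(np.int32)
    return LabelVolume(maps.grid, labels, namespace=Namespace.COARSE), scores


def run_fine(
    maps: ScalarMapSet,
    coarse: LabelVolume,
    h: LabelHierarchy,
    models: dict[int, SegmentationModel],
    config: InferenceConfig | None = None,
) -> dict[int, LabelVolume]:
    """Stage-two prediction: one five-channel model per non-terminal group.

    Each model sees the four maps plus the [0, 1] coarse-mask channel and
    emits labels restricted to its group's final ids (plus background).
    Terminal groups are bypassed — their single labels come straight from
    the coarse stage.
    """
    config = config or InferenceConfig()
    nonterminal = {g.coarse_id for g in h.nonterminal_groups()}
    terminal = {g.coarse_id for g in h.groups if g.terminal}
    extra = set(models) & terminal
    if extra:
        raise ValueError(f"model supplied for terminal group(s) {sorted(extra)}")
    missing = nonterminal - set(models)
    if missing:
        raise ValueError(f"missing model for non-terminal group(s) {sorted(missing)}")

    mask_channel = group_channel(coarse, n_groups=h.n_groups).values
    out: dict[int, LabelVolume] = {}
    for gid in sorted(nonterminal):
        model = models[gid]
        if model.n_in_channels != len(maps.names) + 1:
            raise ValueError(
                f"expected {len(maps.names) + 1} channels for fine stage, "
                f"model takes {model.n_in_channels}"
            )
        _check_channel_order(model, tuple(maps.names) + ("coarse_mask",))
        stack = np.concatenate([maps.stack(), mask_channel[None]], axis=0)
        stack, _ = normalize_channels(
            stack,
            stats=getattr(model, "channel_stats", None),
            skip_channels=(stack.shape[0] - 1,),
        )
        scores = sliding_window_predict(model, stack, config)
        cls = scores.argmax(axis=0)
        class_ids = np.array([0] + sorted(h.group(gid).final_ids), dtype=np.int32)
        out[gid] = LabelVolume(maps.grid, class_ids[cls], namespace=Namespace.FINE)
    return out


# ---------------------------------------------------------------------------
# two-stage orchestration
# ---------------------------------------------------------------------------


def _fine_target(final_labels: np.ndarray, group_ids: list[int]) -> np.ndarray:
    """Map final ids of one group to contiguous class indices (0 = background)."""
    target = np.zeros_like(final_labels, dtype=np.int32)
    for k, fid in enumerate(group_ids, start=1):
        target[final_labels == fid] = k
    return target


def train_two_stage(
    maps: ScalarMapSet,
    final_labels: LabelVolume,
    h: LabelHierarchy,
    coarse_config: TrainConfig | None = None,
    fine_config: TrainConfig | None = None,
    hidden: tuple[int, int] = (32, 64),
    coarse_first_kernel: int = 3,
    fine_first_kernel: int = 1,
    coarse_mask_mode: str = "teacher",
    infer_config: InferenceConfig | None = None,
) -> tuple[TinyConvNet, dict[int, TinyConvNet]]:
    """Train the coarse model then the five fine models, sequentially.

    ``coarse_mask_mode`` selects the fifth channel the fine models train on:
    ``teacher`` uses the reference coarse mask (default), ``predicted`` uses
    the trained coarse model's own output.
    """
    if coarse_mask_mode not in ("teacher", "predicted"):
        raise ValueError(f"unknown coarse_mask_mode {coarse_mask_mode!r}")
    coarse_config = coarse_config or TrainConfig(iterations=300)
    fine_config = fine_config or TrainConfig(
        seed=coarse_config.seed + 1, foreground_fraction=0.7
    )

    coarse_ref = to_coarse(final_labels, h)
    stack, stats = normalize_channels(maps.stack())

    n_coarse_classes = max(g.coarse_id for g in h.groups) + 1
    coarse_model = TinyConvNet(
        n_in_channels=stack.shape[0],
        n_classes=n_coarse_classes,
        hidden=hidden,
        first_kernel=coarse_first_kernel,
        seed=coarse_config.seed,
        channel_names=maps.names,
    )
    coarse_model.channel_stats = stats
    coarse_model, _ = train_stage(
        coarse_model, [(stack, coarse_ref.labels)], coarse_config
    )

    if coarse_mask_mode == "teacher":
        mask_src = coarse_ref
    else:
        mask_src, _ = run_coarse(maps, coarse_model, infer_config)
    mask_channel = group_channel(mask_src, n_groups=h.n_groups).values

    fine_models: dict[int, TinyConvNet] = {}
    for gid in sorted(g.coarse_id for g in h.nonterminal_groups()):
        group_ids = sorted(h.group(gid).final_ids)
        fine_stack = np.concatenate([maps.stack(), mask_channel[None]], axis=0)
        fine_stack, fine_stats = normalize_channels(
            fine_stack, skip_channels=(fine_stack.shape[0] - 1,)
        )
        target = _fine_target(final_labels.labels, group_ids)
        cfg = TrainConfig(**{**fine_config.__dict__, "seed": fine_config.seed + gid})
        model = TinyConvNet(
            n_in_channels=fine_stack.shape[0],
            n_classes=len(group_ids) + 1,
            hidden=hidden,
            first_kernel=fine_first_kernel,
            seed=cfg.seed,
            channel_names=tuple(maps.names) + ("coarse_mask",),
        )
        model.channel_stats = fine_stats
        model, _ = train_stage(model, [(fine_stack, target)], cfg)
        fine_models[gid] = model
    return coarse_model, fine_models


def predict_two_stage(
    maps: ScalarMapSet,
    h: LabelHierarchy,
    coarse_model: SegmentationModel,
    fine_models: dict[int, SegmentationModel],
    config: InferenceConfig | None = None,
) -> tuple[LabelVolume, dict[int, LabelVolume], np.ndarray]:
    """Run both stages; returns (coarse labels, per-group fine labels, coarse scores)."""
    coarse, scores = run_coarse(maps, coarse_model, config)
    fine = run_fine(maps, coarse, h, fine_models, config)
    return coarse, fine, scores
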