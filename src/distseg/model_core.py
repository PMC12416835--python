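"""Backbone contract, reference backbone, loss, schedule and training loop.

The predictor ("backbone") is any object mapping a preprocessed 256x256
patch to a 256x256 distance-map prediction in [0, 1] (sigmoid head).  The
package ships a small convolutional encoder-decoder implemented directly
in numpy (forward and backward passes hand-written), sized to train on a
CPU in minutes; a SAM-style encoder/decoder can be plugged in through
:func:`sam_adapter` when its optional dependencies are available.

Training protocol: AdamW (decoupled weight decay) with a linear learning
rate warm-up over ``warmup_iters`` iterations followed by linear decay to
zero over the remaining fixed horizon (``max_epochs`` x iterations/epoch;
early stopping merely truncates the schedule).  Loss is the pixel-mean L2
between predicted and target distance maps.  Each epoch consumes one
augmented 256x256 patch per training image; early stopping watches the
validation loss with a patience window and a minimum-improvement delta,
and the checkpoint with the lowest validation loss is returned.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from distseg import augment
from distseg.preprocess_tile import PreprocessConfig, preprocess_image


class DegenerateScheduleError(ValueError):
    """Total iteration count does not exceed the warm-up period."""


class OptionalDependencyError(ImportError):
    """An optional backbone dependency (torch / SAM weights) is missing."""


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    lr_init: float = 1e-4
    weight_decay: float = 0.1
    beta1: float = 0.9
    beta2: float = 0.999
    warmup_iters: int = 250
    max_epochs: int = 100
    min_epochs: int = 35
    patience_epochs: int = 7
    min_delta: float = 1e-4
    seed: int = 0
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.min_epochs > self.max_epochs:
            raise ValueError("min_epochs must not exceed max_epochs")
        for name in ("batch_size", "lr_init", "warmup_iters", "max_epochs",
                     "min_epochs", "patience_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr_trace: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


class Backbone(Protocol):
    """Duck-typed training contract every backbone satisfies."""

    def predict(self, patch: np.ndarray) -> np.ndarray: ...
    def loss_and_grads(
        self, x: np.ndarray, y: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]: ...
    def parameters(self) -> dict[str, np.ndarray]: ...
    def state(self) -> dict[str, np.ndarray]: ...
    def load_state(self, state: dict[str, np.ndarray]) -> None: ...


def l2_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean of squared pixel differences."""
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    return float(np.mean((pred.astype(np.float64) - target.astype(np.float64)) ** 2))


def lr_at(iteration: int, total_iterations: int, config: TrainConfig) -> float:
    """Learning rate at a (0-based) iteration.

    Linear ramp from lr_init/warmup to lr_init over the first
    ``warmup_iters`` iterations, then linear decay to zero over the rest;
    continuous at the joint.
    """
    w = config.warmup_iters
    if total_iterations <= w:
        raise DegenerateScheduleError(
            f"total_iterations={total_iterations} must exceed warmup_iters={w}"
        )
    if not 0 <= iteration < total_iterations:
        raise ValueError("iteration out of range")
    if iteration < w:
        return config.lr_init * (iteration + 1) / w
    return config.lr_init * (total_iterations - iteration) / (total_iterations - w)


# ---------------------------------------------------------------------------
# numpy conv-net plumbing
# ---------------------------------------------------------------------------

def _conv3_forward(x, W, b):
    """3x3 same-padding convolution, channels-last.

    x: (B,H,W,C); W: (9*C, F) with the 9 kernel taps ordered row-major.
    The column matrix is built by concatenating the 9 shifted views, which
    is a sequential copy (cache-friendly) feeding a single GEMM.
    """
    B, H, Wd, C = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.concatenate(
        [xp[:, di : di + H, dj : dj + Wd, :] for di in range(3) for dj in range(3)],
        axis=3,
    )
    y = cols.reshape(B * H * Wd, 9 * C) @ W + b
    return y.reshape(B, H, Wd, -1), cols


def _conv3_backward(dy, cols, W, x_shape):
    B, H, Wd, C = x_shape
    F = W.shape[1]
    dym = dy.reshape(B * H * Wd, F)
    colsf = cols.reshape(B * H * Wd, 9 * C)
    dW = colsf.T @ dym
    db = dym.sum(axis=0)
    dcols = (dym @ W.T).reshape(B, H, Wd, 9, C)
    dxp = np.zeros((B, H + 2, Wd + 2, C), dtype=dy.dtype)
    for k, (di, dj) in enumerate((i, j) for i in range(3) for j in range(3)):
        dxp[:, di : di + H, dj : dj + Wd, :] += dcols[:, :, :, k, :]
    return dW, db, dxp[:, 1:-1, 1:-1, :]


def _pool2(x):
    B, H, W, C = x.shape
    return x.reshape(B, H // 2, 2, W // 2, 2, C).mean(axis=(2, 4))


def _pool2_back(dy):
    return np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) * 0.25


def _up2(x):
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _up2_back(dy):
    B, H, W, C = dy.shape
    return dy.reshape(B, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


def _sigmoid(x):
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


_LEAK = 0.05


def _lrelu(x):
    return np.where(x > 0, x, _LEAK * x)


def _lrelu_grad(dact, act):
    return dact * np.where(act > 0, np.float32(1.0), np.float32(_LEAK))


class ReferenceBackbone:
    """Small convolutional encoder-decoder with skip connections.

    Three 2x-downsampling stages (8/16/32 channels), a 32-channel
    bottleneck, and three upsampling stages with encoder skips; 1x1
    sigmoid head.  ~70k parameters, native 256x256 resolution, float32,
    trainable on one CPU core in minutes.
    """

    #: (name, out_channels, in_channels) of every 3x3 conv, head excluded
    _LAYOUT = [
        ("e1", 8, 1),
        ("e2", 16, 8),
        ("e3", 32, 16),
        ("bn", 32, 32),
        ("d3", 16, 32 + 32),
        ("d2", 8, 16 + 16),
        ("d1", 8, 8 + 8),
    ]

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        for name, fout, fin in self._LAYOUT:
            std = np.sqrt(2.0 / (fin * 9))
            self.params[f"{name}.W"] = rng.normal(0, std, (9 * fin, fout)).astype(
                np.float32
            )
            self.params[f"{name}.b"] = np.zeros(fout, dtype=np.float32)
        self.params["head.W"] = rng.normal(0, np.sqrt(1.0 / 8), (8, 1)).astype(
            np.float32
        )
        # start near the background-heavy target prior so the sigmoid is
        # not slammed into saturation by the first updates
        self.params["head.b"] = np.full(1, -2.0, dtype=np.float32)

    # -- contract ----------------------------------------------------------
    @property
    def trainable_parameters(self) -> list[str]:
        return sorted(self.params)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def parameters(self) -> dict[str, np.ndarray]:
        return self.params

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()

    # -- forward / backward ------------------------------------------------
    def _forward(self, x: np.ndarray, keep: bool):
        p = self.params
        cache: dict[str, object] = {}

        def conv(name, inp):
            y, cols = _conv3_forward(inp, p[f"{name}.W"], p[f"{name}.b"])
            if keep:
                cache[name] = (cols, inp.shape)
            return y

        a1 = _lrelu(conv("e1", x))
        p1 = _pool2(a1)
        a2 = _lrelu(conv("e2", p1))
        p2 = _pool2(a2)
        a3 = _lrelu(conv("e3", p2))
        p3 = _pool2(a3)
        ab = _lrelu(conv("bn", p3))
        u3 = np.concatenate([_up2(ab), a3], axis=3)
        a4 = _lrelu(conv("d3", u3))
        u2 = np.concatenate([_up2(a4), a2], axis=3)
        a5 = _lrelu(conv("d2", u2))
        u1 = np.concatenate([_up2(a5), a1], axis=3)
        a6 = _lrelu(conv("d1", u1))
        logits = a6 @ p["head.W"] + p["head.b"]  # a6: (B,H,W,8)
        out = _sigmoid(logits)[..., 0]
        if keep:
            cache["acts"] = (a1, a2, a3, ab, a4, a5, a6, out)
        return out, cache

    def predict(self, patch: np.ndarray) -> np.ndarray:
        """Predict a distance map for one preprocessed 256x256 patch."""
        x = np.asarray(patch, dtype=np.float32)[None, :, :, None]
        out, _ = self._forward(x, keep=False)
        return out[0].astype(np.float64)

    def predict_batch(self, patches: np.ndarray) -> np.ndarray:
        x = np.asarray(patches, dtype=np.float32)[:, :, :, None]
        out, _ = self._forward(x, keep=False)
        return out.astype(np.float64)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """L2 loss and parameter gradients for a batch.

        x, y: (B, 256, 256) preprocessed patches / targets.
        """
        xb = np.asarray(x, dtype=np.float32)[:, :, :, None]
        yb = np.asarray(y, dtype=np.float32)
        out, cache = self._forward(xb, keep=True)
        diff = out - yb
        loss = float(np.mean(diff.astype(np.float64) ** 2))
        a1, a2, a3, ab, a4, a5, a6, _ = cache["acts"]
        p = self.params
        grads: dict[str, np.ndarray] = {}

        dlogits = ((2.0 / diff.size) * diff * out * (1.0 - out))[..., None]
        B, H, W = out.shape
        grads["head.W"] = a6.reshape(-1, 8).T @ dlogits.reshape(-1, 1)
        grads["head.b"] = np.array([dlogits.sum()], dtype=np.float32)
        da6 = dlogits @ p["head.W"].T

        def conv_back(name, dact, act):
            d = _lrelu_grad(dact, act)
            cols, in_shape = cache[name]
            dW, db, dx = _conv3_backward(d, cols, p[f"{name}.W"], in_shape)
            grads[f"{name}.W"] = dW
            grads[f"{name}.b"] = db
            return dx

        du1 = conv_back("d1", da6, a6)
        da5, da1_skip = _up2_back(du1[..., :8]), du1[..., 8:]
        du2 = conv_back("d2", da5, a5)
        da4, da2_skip = _up2_back(du2[..., :16]), du2[..., 16:]
        du3 = conv_back("d3", da4, a4)
        dab, da3_skip = _up2_back(du3[..., :32]), du3[..., 32:]
        dp3 = conv_back("bn", dab, ab)
        da3 = _pool2_back(dp3) + da3_skip
        dp2 = conv_back("e3", da3, a3)
        da2 = _pool2_back(dp2) + da2_skip
        dp1 = conv_back("e2", da2, a2)
        da1 = _pool2_back(dp1) + da1_skip
        conv_back("e1", da1, a1)
        return loss, grads


def reference_backbone(seed: int = 0) -> ReferenceBackbone:
    """Seeded construction of the reference backbone."""
    return ReferenceBackbone(seed=seed)


# ---------------------------------------------------------------------------
# optimizer and training loop
# ---------------------------------------------------------------------------

class AdamW:
    """AdamW with decoupled weight decay (biases excluded from decay)."""

    def __init__(self, params: dict[str, np.ndarray], config: TrainConfig):
        self.cfg = config
        self.m = {k: np.zeros_like(v, dtype=np.float32) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float32) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float):
        c = self.cfg
        self.t += 1
        b1t = 1.0 - c.beta1**self.t
        b2t = 1.0 - c.beta2**self.t
        for k, p in params.items():
            g = grads[k].astype(np.float32)
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p -= lr * mhat / (np.sqrt(vhat) + 1e-8)
            if not k.endswith(".b"):
                p -= lr * c.weight_decay * p


def _center_crop(arr: np.ndarray, size: int = 256) -> np.ndarray:
    from distseg.preprocess_tile import reflect_pad

    h, w = arr.shape
    if h < size or w < size:
        arr = reflect_pad(arr, (0, max(size - h, 0), 0, max(size - w, 0)))
        h, w = arr.shape
    r = (h - size) // 2
    c = (w - size) // 2
    return arr[r : r + size, c : c + size]


def _validation_loss(
    backbone, val_set: Sequence[tuple[np.ndarray, np.ndarray]], pp: PreprocessConfig
) -> float:
    losses = []
    for img, dmap in val_set:
        x = preprocess_image(_center_crop(img), pp)
        y = _center_crop(dmap)
        losses.append(l2_loss(backbone.predict(x), y))
    return float(np.mean(losses))


def split_dataset(
    dataset: Sequence, seed: int, val_fraction: float
) -> tuple[list, list]:
    """Seeded shuffle split into (train, val); val gets >= 1 item."""
    idx = np.random.default_rng(seed).permutation(len(dataset))
    n_val = max(1, int(round(val_fraction * len(dataset))))
    val = [dataset[i] for i in idx[:n_val]]
    train = [dataset[i] for i in idx[n_val:]]
    return train, val


def train(
    backbone,
    dataset: Sequence[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
    preprocess_config: PreprocessConfig | None = None,
) -> tuple[dict[str, np.ndarray], TrainHistory]:
    """Train a backbone on (image, distance-map) pairs.

    The dataset is split into train/val by a seeded shuffle; every epoch
    draws one augmented patch per training image (see
    :func:`distseg.augment.epoch_sampler`), patches are CLAHE +
    z-normalized, and AdamW updates run under the warm-up/linear-decay
    schedule.  Stops when the validation loss has not improved by more
    than ``min_delta`` for ``patience_epochs`` consecutive epochs (never
    before ``min_epochs``), or at ``max_epochs``.  Returns the parameter
    snapshot with the lowest validation loss and the full history.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    pp = preprocess_config or PreprocessConfig()
    train_set, val_set = split_dataset(dataset, config.seed, config.val_fraction)
    if not train_set:
        raise ValueError("dataset too small to split")
    iters_per_epoch = int(np.ceil(len(train_set) / config.batch_size))
    total_iters = config.max_epochs * iters_per_epoch
    if total_iters <= config.warmup_iters:
        raise DegenerateScheduleError(
            f"schedule horizon {total_iters} iterations does not exceed "
            f"warmup_iters={config.warmup_iters}"
        )

    opt = AdamW(backbone.parameters(), config)
    history = TrainHistory()
    best_val = np.inf
    best_state = backbone.state()
    iteration = 0
    seed_root = np.random.SeedSequence(config.seed)
    epoch_seeds = seed_root.generate_state(config.max_epochs + 1) % (2**31)

    for epoch in range(1, config.max_epochs + 1):
        batch_x: list[np.ndarray] = []
        batch_y: list[np.ndarray] = []
        epoch_losses: list[float] = []

        def flush():
            nonlocal iteration
            if not batch_x:
                return
            lr = lr_at(iteration, total_iters, config)
            loss, grads = backbone.loss_and_grads(
                np.stack(batch_x), np.stack(batch_y)
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, "
                    f"iteration {iteration}"
                )
            opt.step(backbone.parameters(), grads, lr)
            history.lr_trace.append(lr)
            epoch_losses.append(loss)
            iteration += 1
            batch_x.clear()
            batch_y.clear()

        for patch, target in augment.epoch_sampler(
            train_set, int(epoch_seeds[epoch])
        ):
            batch_x.append(preprocess_image(patch, pp))
            batch_y.append(target)
            if len(batch_x) == config.batch_size:
                flush()
        flush()

        val_loss = _validation_loss(backbone, val_set, pp)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)

        if val_loss < best_val - config.min_delta:
            best_val = val_loss
            best_state = backbone.state()
            history.best_epoch = epoch

        history.stopped_epoch = epoch
        if (
            epoch >= config.min_epochs
            and epoch - history.best_epoch >= config.patience_epochs
        ):
            break

    backbone.load_state(best_state)
    return best_state, history


def save_checkpoint(path: str | Path, state: dict[str, np.ndarray],
                    config: TrainConfig, history: TrainHistory) -> None:
    """Parameter snapshot (.npz) plus a JSON sidecar (config + history)."""
    path = Path(path)
    np.savez(path, **state)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"config": asdict(config), "history": asdict(history)}, indent=1)
    )


def load_checkpoint(path: str | Path) -> ReferenceBackbone:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        state = {k: data[k] for k in data.files}
    bb = ReferenceBackbone(seed=0)
    bb.load_state(state)
    return bb


def sam_adapter(weights_path: str | Path):
    """Adapter exposing a SAM-style encoder/decoder under the backbone
    contract: the 256x256 patch is bilinearly upsampled to the encoder's
    native 1024x1024 input, the mask decoder runs with the frozen default
    prompt embedding, and a sigmoid head returns the native 256x256 map.
    Trainable groups are the image encoder and mask decoder; the prompt
    encoder is frozen.

    This is an optional feature: it requires ``torch``, the
    ``segment_anything`` package and a local SAM-base checkpoint, none of
    which the core pipeline depends on.
    """
    try:
        import torch  # noqa: F401
        import segment_anything  # noqa: F401
    except ImportError as exc:
        raise OptionalDependencyError(
            "sam_adapter requires the optional dependencies 'torch' and "
            "'segment_anything'; install them and provide SAM-base weights "
            "to use a SAM backbone. The reference backbone needs neither."
        ) from exc
    weights_path = Path(weights_path)
    if not weights_path.exists():
        raise OptionalDependencyError(
            f"SAM weights not found at {weights_path}; download a SAM-base "
            "checkpoint to use this optional backbone."
        )
    return _build_sam_backbone(weights_path)


def _build_sam_backbone(weights_path: Path):  # pragma: no cover - optional path
    import torch
    from segment_anything import sam_model_registry

    from distseg.preprocess_tile import downsample_pred, upsample_patch

    sam = sam_model_registry["vit_b"](checkpoint=str(weights_path))
    sam.eval()
    for p in sam.prompt_encoder.parameters():
        p.requires_grad_(False)

    class SamBackbone:
        trainable_parameters = [
            n
            for n, p in sam.named_parameters()
            if not n.startswith("prompt_encoder")
        ]

        def predict(self, patch: np.ndarray) -> np.ndarray:
            big = upsample_patch(np.asarray(patch, dtype=np.float64), 4)
            x = torch.as_tensor(big, dtype=torch.float32)[None, None]
            x = x.repeat(1, 3, 1, 1)
            with torch.no_grad():
                emb = sam.image_encoder(x)
                sparse, dense = sam.prompt_encoder(
                    points=None, boxes=None, masks=None
                )
                low_res, _ = sam.mask_decoder(
                    image_embeddings=emb,
                    image_pe=sam.prompt_encoder.get_dense_pe(),
                    sparse_prompt_embeddings=sparse,
                    dense_prompt_embeddings=dense,
                    multimask_output=False,
                )
                out = torch.sigmoid(low_res)[0, 0].numpy()
            return downsample_pred(out, 256) if out.shape != (256, 256) else out

    return SamBackbone()
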