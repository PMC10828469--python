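"""LinkNet-style fully convolutional encoder-decoder for ordinal masks.

The network maps a normalized RGB tile to a (K-1)-channel map of logits at
the input resolution.  It follows the canonical LinkNet layout built on
ResNet-18-style basic blocks:

* stem: 7x7 conv stride 2 -> BN -> ReLU -> 3x3 max-pool stride 2 (H/4)
* encoder: four stages of 2 residual basic blocks at widths
  w, 2w, 4w, 8w; stages 2-4 halve resolution (H/8, H/16, H/32)
* decoder: four blocks (1x1 conv to width/4 -> 3x3 transposed conv ->
  1x1 conv to the next-shallower width); decoders 4-3-2 upsample x2 and
  their outputs are added element-wise to encoder stages 3-2-1 (the
  "link" skips); decoder 1 keeps stride 1 so the head's two stride-2
  transposed convs return exactly to input resolution
* head: 3x3 transposed conv stride 2 to w/2, 3x3 conv, 2x2 transposed
  conv stride 2 to the output channels

The probability head is per-channel sigmoid by default: ordinal chain
targets such as (1,1,0) are multi-hot, so channels must be independent.
A softmax-across-channels head is retained as a configuration option.
``base_width`` scales every stage so a desk-scale model (width 8) trains
in minutes while the layout matches the full-width (64) network.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import F32

__all__ = [
    "ModelConfig",
    "LinkNet",
    "init_model",
    "forward",
    "predict_probability_mask",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 3
    out_channels: int = 3
    base_width: int = 64
    encoder_stage_widths: tuple[int, ...] | None = None
    blocks_per_stage: int = 2
    activation_head: str = "sigmoid"

    def __post_init__(self) -> None:
        if self.out_channels < 1:
            raise ValueError("out_channels must be >= 1")
        if self.base_width < 4 or self.base_width % 4:
            raise ValueError("base_width must be a positive multiple of 4")
        widths = self.encoder_stage_widths or tuple(self.base_width * m for m in (1, 2, 4, 8))
        if len(widths) != 4 or any(w <= 0 or w % 4 for w in widths):
            raise ValueError(f"need 4 positive multiples of 4 as stage widths, got {widths}")
        if widths[0] != self.base_width:
            raise ValueError("first stage width must equal base_width")
        object.__setattr__(self, "encoder_stage_widths", tuple(widths))
        if self.activation_head not in ("sigmoid", "softmax"):
            raise ValueError(f"unknown activation head {self.activation_head!r}")

    def to_dict(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "out_channels": self.out_channels,
            "base_width": self.base_width,
            "encoder_stage_widths": list(self.encoder_stage_widths),
            "blocks_per_stage": self.blocks_per_stage,
            "activation_head": self.activation_head,
        }


class BasicBlock(nn.Layer):
    """ResNet basic block: two 3x3 convs with an additive shortcut."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(cin, cout, 3, stride, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(cout, cout, 3, 1, 1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.relu_out = nn.ReLU()
        if stride != 1 or cin != cout:
            self.shortcut = nn.Sequential(
                nn.Conv2d(cin, cout, 1, stride, 0, bias=False, rng=rng), nn.BatchNorm2d(cout)
            )
        else:
            self.shortcut = None

    def params(self):
        out = (
            self.conv1.params()
            + self.bn1.params()
            + self.conv2.params()
            + self.bn2.params()
        )
        if self.shortcut is not None:
            out += self.shortcut.params()
        return out

    def forward(self, x, training=False):
        main = self.bn2.forward(
            self.conv2.forward(
                self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training), training), training),
                training,
            ),
            training,
        )
        sc = x if self.shortcut is None else self.shortcut.forward(x, training)
        return self.relu_out.forward(main + sc, training)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        d_main = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(d))))
        )
        d_sc = d if self.shortcut is None else self.shortcut.backward(d)
        return d_main + d_sc


def _decoder_block(cin: int, cout: int, stride: int, rng: np.random.Generator) -> nn.Sequential:
    mid = cin // 4
    return nn.Sequential(
        nn.Conv2d(cin, mid, 1, 1, 0, bias=False, rng=rng),
        nn.BatchNorm2d(mid),
        nn.ReLU(),
        nn.ConvTranspose2d(
            mid, mid, 3, stride, 1, output_padding=stride - 1, bias=False, rng=rng
        ),
        nn.BatchNorm2d(mid),
        nn.ReLU(),
        nn.Conv2d(mid, cout, 1, 1, 0, bias=False, rng=rng),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
    )


class LinkNet:
    """Encoder-decoder with additive skip links; see module docstring."""

    DIVISOR = 32  # total stride of the deepest encoder stage

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        w = config.base_width
        w1, w2, w3, w4 = config.encoder_stage_widths
        self.stem = nn.Sequential(
            nn.Conv2d(config.in_channels, w, 7, 2, 3, bias=False, rng=rng),
            nn.BatchNorm2d(w),
            nn.ReLU(),
        )
        self.pool = nn.MaxPool2d(3, 2, 1)

        def stage(cin, cout, stride):
            blocks = [BasicBlock(cin, cout, stride, rng)]
            for _ in range(config.blocks_per_stage - 1):
                blocks.append(BasicBlock(cout, cout, 1, rng))
            return nn.Sequential(*blocks)

        self.enc1 = stage(w, w1, 1)
        self.enc2 = stage(w1, w2, 2)
        self.enc3 = stage(w2, w3, 2)
        self.enc4 = stage(w3, w4, 2)
        self.dec4 = _decoder_block(w4, w3, 2, rng)
        self.dec3 = _decoder_block(w3, w2, 2, rng)
        self.dec2 = _decoder_block(w2, w1, 2, rng)
        self.dec1 = _decoder_block(w1, w1, 1, rng)
        self.head = nn.Sequential(
            nn.ConvTranspose2d(w1, w // 2, 3, 2, 1, output_padding=1, bias=False, rng=rng),
            nn.BatchNorm2d(w // 2),
            nn.ReLU(),
            nn.Conv2d(w // 2, w // 2, 3, 1, 1, bias=False, rng=rng),
            nn.BatchNorm2d(w // 2),
            nn.ReLU(),
            nn.ConvTranspose2d(w // 2, config.out_channels, 2, 2, 0, bias=True, rng=rng),
        )
        self._modules = [
            self.stem,
            self.enc1,
            self.enc2,
            self.enc3,
            self.enc4,
            self.dec4,
            self.dec3,
            self.dec2,
            self.dec1,
            self.head,
        ]

    # -- parameter plumbing ------------------------------------------------
    def params(self) -> list[nn.Param]:
        return [p for m in self._modules for p in m.params()]

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def _bn_layers(self) -> list[nn.BatchNorm2d]:
        out = []

        def walk(layer):
            if isinstance(layer, nn.BatchNorm2d):
                out.append(layer)
            elif isinstance(layer, nn.Sequential):
                for sub in layer.layers:
                    walk(sub)
            elif isinstance(layer, BasicBlock):
                for sub in (layer.bn1, layer.bn2):
                    out.append(sub)
                if layer.shortcut is not None:
                    walk(layer.shortcut)

        for m in self._modules:
            walk(m)
        return out

    def set_bn_update(self, flag: bool) -> None:
        for bn in self._bn_layers():
            bn.update_stats = flag

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param_{i:04d}": p.data for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._bn_layers()):
            state[f"bn_{i:04d}_mean"] = bn.running_mean
            state[f"bn_{i:04d}_var"] = bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            arr = np.asarray(state[f"param_{i:04d}"], dtype=F32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
            p.grad = np.zeros_like(p.data)
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean = np.asarray(state[f"bn_{i:04d}_mean"], dtype=F32).copy()
            bn.running_var = np.asarray(state[f"bn_{i:04d}_var"], dtype=F32).copy()

    # -- forward/backward --------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.dtype != np.float64:  # float64 kept for high-precision checks
            x = np.asarray(x, dtype=F32)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, H, W) input, got shape {x.shape}"
            )
        h, w = x.shape[2], x.shape[3]
        if h % self.DIVISOR or w % self.DIVISOR:
            raise ValueError(
                f"input spatial dims ({h}, {w}) must be divisible by {self.DIVISOR}; "
                "pad or crop the tile to a multiple of 32"
            )
        return np.ascontiguousarray(x)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = self._check_input(x)
        f0 = self.stem.forward(x, training)
        p0 = self.pool.forward(f0, training)
        e1 = self.enc1.forward(p0, training)
        e2 = self.enc2.forward(e1, training)
        e3 = self.enc3.forward(e2, training)
        e4 = self.enc4.forward(e3, training)
        d4 = self.dec4.forward(e4, training) + e3
        d3 = self.dec3.forward(d4, training) + e2
        d2 = self.dec2.forward(d3, training) + e1
        d1 = self.dec1.forward(d2, training)
        return self.head.forward(d1, training)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g_d1 = self.head.backward(np.asarray(dlogits))
        g_d2 = self.dec1.backward(g_d1)
        g_d3 = self.dec2.backward(g_d2)
        g_d4 = self.dec3.backward(g_d3)
        g_e4 = self.dec4.backward(g_d4)
        g_e3 = self.enc4.backward(g_e4) + g_d4
        g_e2 = self.enc3.backward(g_e3) + g_d3
        g_e1 = self.enc2.backward(g_e2) + g_d2
        g_p0 = self.enc1.backward(g_e1)
        g_f0 = self.pool.backward(g_p0)
        return self.stem.backward(g_f0)

    def activate(self, logits: np.ndarray) -> np.ndarray:
        if self.config.activation_head == "softmax":
            return nn.softmax_channels(logits)
        return nn.sigmoid(logits)


def init_model(config: ModelConfig, seed: int = 0) -> LinkNet:
    """Construct a model with seeded weight initialization."""
    return LinkNet(config, seed)


def forward(model: LinkNet, batch: np.ndarray) -> np.ndarray:
    """Inference-mode logits for an (N, 3, H, W) batch (deterministic)."""
    return model.forward(batch, training=False)


def predict_probability_mask(model: LinkNet, tile_pixels: np.ndarray) -> np.ndarray:
    """Per-pixel, per-channel probabilities in [0,1] for one normalized tile.

    ``tile_pixels`` may be (H, W, 3) or (3, H, W); returns (K-1, H, W).
    """
    x = np.asarray(tile_pixels, dtype=F32)
    if x.ndim != 3:
        raise ValueError(f"expected one tile, got shape {x.shape}")
    if x.shape[2] == model.config.in_channels:
        x = x.transpose(2, 0, 1)
    logits = model.forward(x[None], training=False)[0]
    return model.activate(logits)


# -- checkpointing ---------------------------------------------------------


def save_checkpoint(
    path: str | Path,
    model: LinkNet,
    meta: dict | None = None,
    arrays: dict[str, np.ndarray] | None = None,
) -> None:
    """Self-describing checkpoint: parameters + config + arbitrary metadata.

    ``meta`` (JSON-serializable) typically carries the age schedule and the
    preprocessing configuration; ``arrays`` can hold the fitted quantile
    reference so a checkpoint scores new slides without retraining.
    """
    path = Path(path)
    payload = dict(model.state_dict())
    full_meta = {"model_config": model.config.to_dict()}
    if meta:
        full_meta.update(meta)
    if arrays:
        for k, v in arrays.items():
            payload[f"extra_{k}"] = np.asarray(v)
    payload["meta_json"] = np.frombuffer(
        json.dumps(full_meta, sort_keys=True).encode(), dtype=np.uint8
    )
    buf = io.BytesIO()
    np.savez(buf, **payload)
    path.write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path) -> tuple[LinkNet, dict, dict[str, np.ndarray]]:
    """Load a checkpoint; returns (model, meta, extra arrays)."""
    with np.load(Path(path), allow_pickle=False) as npz:
        data = {k: npz[k] for k in npz.files}
    meta = json.loads(bytes(data.pop("meta_json")).decode())
    config = ModelConfig(
        in_channels=meta["model_config"]["in_channels"],
        out_channels=meta["model_config"]["out_channels"],
        base_width=meta["model_config"]["base_width"],
        encoder_stage_widths=tuple(meta["model_config"]["encoder_stage_widths"]),
        blocks_per_stage=meta["model_config"]["blocks_per_stage"],
        activation_head=meta["model_config"]["activation_head"],
    )
    model = LinkNet(config, seed=0)
    extras = {k[len("extra_") :]: v for k, v in data.items() if k.startswith("extra_")}
    state = {k: v for k, v in data.items() if not k.startswith("extra_")}
    model.load_state_dict(state)
    return model, meta, extras
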