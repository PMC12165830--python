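"""The virion-protein CNN head over fixed-length embeddings.

Architecture (binary head shown; the 7-class head is identical apart from
the final layer width):

    (N, 1024) -> reshape (N, 1, 1024)
              -> Conv1d(32 filters, kernel 3, stride 1)   -> (N, 32, 1022)
              -> BatchNorm(32) -> ReLU
              -> MaxPool1d(kernel 3, stride 2)            -> (N, 32, 510)
              -> Flatten                                  -> (N, 16320)
              -> Dense(64) -> BatchNorm(64) -> ReLU
              -> Dense(n_classes)                          -> logits

No padding anywhere (that is what makes 1024 -> 1022 -> 510). The network
emits raw logits; the loss applies the softmax. The dense layer after the
flatten infers its input width from the shape chain at build time, so
non-default embedding dimensions work unchanged.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn


@dataclass(frozen=True)
class ClassifierConfig:
    input_dim: int = 1024
    conv_filters: int = 32
    conv_kernel: int = 3
    conv_stride: int = 1
    pool_kernel: int = 3
    pool_stride: int = 2
    hidden_units: int = 64
    n_classes: int = 2
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("input_dim", "conv_filters", "conv_kernel", "conv_stride",
                     "pool_kernel", "pool_stride", "hidden_units"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.activation not in ("relu", "none"):
            raise ValueError(f"unsupported activation {self.activation!r}")


def conv_out_len(length: int, kernel: int, stride: int, padding: int = 0) -> int:
    """Output length of a valid conv/pool window pass."""
    if length + 2 * padding < kernel:
        raise ValueError(
            f"input length {length} (+2x{padding} padding) shorter than kernel {kernel}"
        )
    return (length + 2 * padding - kernel) // stride + 1


def shape_chain(config: ClassifierConfig) -> dict[str, tuple]:
    """Symbolic trace of every intermediate output shape (batch size N)."""
    l_conv = conv_out_len(config.input_dim, config.conv_kernel, config.conv_stride)
    l_pool = conv_out_len(l_conv, config.pool_kernel, config.pool_stride)
    flat = config.conv_filters * l_pool
    return {
        "input": ("N", config.input_dim),
        "reshape": ("N", 1, config.input_dim),
        "conv": ("N", config.conv_filters, l_conv),
        "pool": ("N", config.conv_filters, l_pool),
        "flatten": ("N", flat),
        "hidden": ("N", config.hidden_units),
        "logits": ("N", config.n_classes),
    }


@dataclass
class ModelState:
    """A built network: config, layer stack and training metadata."""

    config: ClassifierConfig
    network: nn.Sequential
    classes: tuple[str, ...] = ()
    epochs_run: int = 0
    best_val_loss: float = float("nan")

    def forward(self, batch: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(batch, dtype=nn.DTYPE)
        if x.ndim != 2 or x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"batch width {x.shape[-1] if x.ndim == 2 else x.shape} != "
                f"model input_dim {self.config.input_dim}"
            )
        return self.network.forward(x, training=training)


def build_model(config: ClassifierConfig, classes: tuple[str, ...] = ()) -> ModelState:
    """Construct the network with seeded parameter initialization."""
    rng = np.random.default_rng(config.seed)
    chain = shape_chain(config)
    flat = chain["flatten"][1]

    def act() -> nn.Layer:
        return nn.ReLU() if config.activation == "relu" else nn.Identity()

    network = nn.Sequential([
        nn.Reshape1ch(),
        nn.Conv1d(1, config.conv_filters, config.conv_kernel, config.conv_stride, rng=rng),
        nn.BatchNorm(config.conv_filters),
        act(),
        nn.MaxPool1d(config.pool_kernel, config.pool_stride),
        nn.Flatten(),
        nn.Dense(flat, config.hidden_units, rng=rng),
        nn.BatchNorm(config.hidden_units),
        act(),
        nn.Dense(config.hidden_units, config.n_classes, rng=rng),
    ])
    if classes and len(classes) != config.n_classes:
        raise ValueError("classes tuple length must equal n_classes")
    return ModelState(config=config, network=network, classes=tuple(classes))


def forward(model: ModelState, batch: np.ndarray) -> np.ndarray:
    """Evaluation-mode logits for a batch of embedding vectors."""
    return model.forward(batch, training=False)


def save_model(model: ModelState, path: str | Path) -> None:
    """Self-describing checkpoint: config + classes + all parameter tensors."""
    meta = {
        "config": asdict(model.config),
        "classes": list(model.classes),
        "epochs_run": model.epochs_run,
        "best_val_loss": model.best_val_loss,
    }
    arrays = model.network.state()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path: str | Path) -> ModelState:
    p = Path(path)
    if not p.exists():  # np.savez may have appended .npz
        with_ext = p.with_name(p.name + ".npz")
        if with_ext.exists():
            p = with_ext
    with np.load(p) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = build_model(ClassifierConfig(**meta["config"]), tuple(meta["classes"]))
    model.network.load_state(state)
    model.epochs_run = meta["epochs_run"]
    model.best_val_loss = meta["best_val_loss"]
    return model
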