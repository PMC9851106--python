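"""Single-task and multi-task CNN-LSTM architectures.

The encoder is a wave-wise 1x1 convolution (one kernel touches one time
step) with 50 filters, ReLU and dropout; it maps each task's feature width
to a common dimension so tasks of different widths share downstream
layers.  The recurrent trunk is four stacked blocks — recurrent layer,
Tanh, dropout — with units 50, 10, 10, 10; the cell is LSTM by default
(GRU/RNN selectable for the baselines).  Classification reads the final
wave's hidden state through one fully connected layer and a sigmoid.

The multi-task model keeps one encoder and one head per task and *hard-
shares* the recurrent trunk: both tasks' forward passes run through the
same parameter storage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Dense, Dropout, Module, Recurrent, Tensor, make_cell, relu, sigmoid, tanh

__all__ = [
    "ModelConfig",
    "Encoder",
    "RecurrentStack",
    "SingleTaskNet",
    "MultiTaskNet",
    "build_encoder",
    "build_recurrent_stack",
    "build_single_task_model",
    "build_multi_task_model",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    conv_filters: int = 50
    lstm_units: list[int] = field(default_factory=lambda: [50, 10, 10, 10])
    dropout: float = 0.3
    cell_type: str = "LSTM"

    def __post_init__(self) -> None:
        if self.conv_filters < 1 or not self.lstm_units:
            raise ValueError("conv_filters and lstm_units must be nonempty/positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


class Encoder(Module):
    """Wave-wise 1x1 convolutional encoder: [N, T, F_in] -> [N, T, filters]."""

    def __init__(self, n_features_in: int, config: ModelConfig, rng: np.random.Generator):
        if n_features_in < 1:
            raise ValueError("n_features_in must be >= 1")
        self.n_features_in = n_features_in
        self.dense = Dense(n_features_in, config.conv_filters, rng)
        self.drop = Dropout(config.dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.drop(relu(self.dense(x)))


class RecurrentStack(Module):
    """Stacked recurrent blocks: cell -> Tanh -> dropout, lower to upper."""

    def __init__(self, n_in: int, config: ModelConfig, rng: np.random.Generator):
        self.blocks: list[Module] = []
        self.drops: list[Dropout] = []
        d = n_in
        for units in config.lstm_units:
            self.blocks.append(Recurrent(make_cell(config.cell_type, d, units, rng)))
            self.drops.append(Dropout(config.dropout, rng))
            d = units
        self.n_out = d

    def __call__(self, x: Tensor) -> Tensor:
        for block, drop in zip(self.blocks, self.drops):
            x = drop(tanh(block(x)))
        return x


class SingleTaskNet(Module):
    """(optional encoder) -> recurrent stack -> final wave -> dense -> sigmoid."""

    def __init__(
        self,
        n_features_in: int,
        config: ModelConfig,
        use_cnn: bool = True,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.config = config
        self.use_cnn = use_cnn
        self.encoder = Encoder(n_features_in, config, rng) if use_cnn else None
        stack_in = config.conv_filters if use_cnn else n_features_in
        self.stack = RecurrentStack(stack_in, config, rng)
        self.head = Dense(self.stack.n_out, 1, rng)
        self.n_features_in = n_features_in

    def __call__(self, x) -> Tensor:
        x = Tensor(x) if not isinstance(x, Tensor) else x
        if x.shape[-1] != self.n_features_in:
            raise ValueError(
                f"expected feature width {self.n_features_in}, got {x.shape[-1]}"
            )
        if self.encoder is not None:
            x = self.encoder(x)
        h = self.stack(x)
        last = h[:, h.shape[1] - 1, :]
        return sigmoid(self.head(last).reshape(-1))


class MultiTaskNet(Module):
    """Per-task encoders and heads around one hard-shared recurrent trunk."""

    def __init__(
        self,
        n_features_by_task: dict[str, int],
        config: ModelConfig,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.config = config
        self.tasks = list(n_features_by_task)
        self.encoders = {
            task: Encoder(n_in, config, rng)
            for task, n_in in n_features_by_task.items()
        }
        widths = {config.conv_filters}
        if len(widths) != 1:
            raise ValueError("encoders must share one output width")
        self.stack = RecurrentStack(config.conv_filters, config, rng)
        self.heads = {task: Dense(self.stack.n_out, 1, rng) for task in self.tasks}

    def __call__(self, x, task: str) -> Tensor:
        if task not in self.encoders:
            raise KeyError(f"unknown task {task!r}")
        x = Tensor(x) if not isinstance(x, Tensor) else x
        enc = self.encoders[task]
        if x.shape[-1] != enc.n_features_in:
            raise ValueError(
                f"task {task!r} expects feature width {enc.n_features_in}, "
                f"got {x.shape[-1]}"
            )
        h = self.stack(enc(x))
        last = h[:, h.shape[1] - 1, :]
        return sigmoid(self.heads[task](last).reshape(-1))

    def shared_parameters(self):
        return self.stack.parameters()

    def task_parameters(self, task: str):
        return self.encoders[task].parameters() + self.heads[task].parameters()


def save_checkpoint(model, path) -> None:
    """Save parameters with the architecture config embedded."""
    import json

    from dataclasses import asdict

    if isinstance(model, SingleTaskNet):
        meta = {
            "kind": "single",
            "config": asdict(model.config),
            "n_features_in": model.n_features_in,
            "use_cnn": model.use_cnn,
        }
    elif isinstance(model, MultiTaskNet):
        meta = {
            "kind": "multi",
            "config": asdict(model.config),
            "n_features_by_task": {
                t: enc.n_features_in for t, enc in model.encoders.items()
            },
        }
    else:
        raise TypeError(f"cannot checkpoint {type(model).__name__}")
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path):
    """Rebuild a model from a checkpoint file."""
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arrays = [data[f"p{i}"] for i in range(len(data.files) - 1)]
    config = ModelConfig(**meta["config"])
    if meta["kind"] == "single":
        model = SingleTaskNet(meta["n_features_in"], config, use_cnn=meta["use_cnn"])
    else:
        model = MultiTaskNet(meta["n_features_by_task"], config)
    model.load_state_arrays(arrays)
    model.eval()
    return model


# Thin functional wrappers matching the module surface.
def build_encoder(n_features_in: int, config: ModelConfig, seed: int = 0) -> Encoder:
    return Encoder(n_features_in, config, np.random.default_rng(seed))


def build_recurrent_stack(config: ModelConfig, n_in: int | None = None, seed: int = 0):
    return RecurrentStack(
        config.conv_filters if n_in is None else n_in, config, np.random.default_rng(seed)
    )


def build_single_task_model(
    n_features_in: int, config: ModelConfig, use_cnn: bool = True, seed: int = 0
) -> SingleTaskNet:
    return SingleTaskNet(n_features_in, config, use_cnn=use_cnn, seed=seed)


def build_multi_task_model(
    n_features_by_task: dict[str, int], config: ModelConfig, seed: int = 0
) -> MultiTaskNet:
    if len(n_features_by_task) < 2:
        raise ValueError("multi-task model needs at least two tasks")
    return MultiTaskNet(n_features_by_task, config, seed=seed)
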