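"""1D pre-activation residual network with a size-reducing front stage.

The architecture classifies 64-sample (6.4 s at 10 Hz) windows of NIRS
hemodynamic signals into three breathing conditions. It is a 1D adaptation
of the pre-activation residual network with bottleneck units
(``x_{l+1} = F(x_l, W_l) + x_l``, batch norm and ReLU preceding each
convolution), with an extra stride-2 bottleneck unit ("Stage 1") inserted
between the stem and the main stages to halve the temporal length while
building a wide-receptive-field feature. Variants:

* ``stage1_k5`` — Stage 1 with a 1x5 spatial kernel (the proposed model);
* ``stage1_k3`` — Stage 1 with a 1x3 kernel;
* ``ds`` — no Stage 1; the caller feeds inputs pre-downsampled to half
  length (see :func:`downsample_half`).

Layout for the default configuration (input 1x64, base width 16)::

    Stage 0   1x5 conv, 16 ch, stride 1          length 64
    Stage 1   bottleneck 1x1/1xk/1x1, 16 ch, /2  length 64 -> 32
    Stage 2   12 x bottleneck (16,16,64)         length 32
    Stage 3   12 x bottleneck (32,32,128), /2    length 32 -> 16
    Stage 4   12 x bottleneck (64,64,256), /2    length 16 -> 8
    BN+ReLU, global average pool -> 256, fully connected -> 3 classes

Counting conventions (documented because the headline figures depend on
them): *weighted layers* are convolutional and fully connected layers only
(113 for ``stage1_k5`` with 12 blocks per stage); *FLOPs* are 2 per
multiply-accumulate over main-path convolutions and the classifier,
excluding projection shortcuts, batch norm, ReLU and pooling; the headline
*parameter* figure follows the same main-path convention, while the full
trainable total (including projections) is also reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import (
    BatchNorm1d,
    Conv1d,
    GlobalAvgPool1d,
    Linear,
    Param,
    ReLU,
)

__all__ = [
    "ArchitectureConfig",
    "ResNet1D",
    "LayerAccount",
    "build_model",
    "forward",
    "downsample_half",
    "count_weighted_layers",
    "count_parameters",
    "count_flops",
    "layer_account",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("ds", "stage1_k3", "stage1_k5")


@dataclass(frozen=True)
class ArchitectureConfig:
    """Structural description of one model variant.

    ``input_length`` is the temporal length the network itself sees: 64 for
    the Stage-1 variants, 32 for ``ds`` (whose caller halves the signal
    first). ``base_width`` scales every stage's channel counts together.
    """

    variant: str = "stage1_k5"
    input_channels: int = 1
    input_length: int = 64
    num_classes: int = 3
    blocks_per_stage: int = 12
    base_width: int = 16

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.input_channels < 1 or self.num_classes < 2:
            raise ValueError("input_channels must be >= 1 and num_classes >= 2")
        if self.blocks_per_stage < 1:
            raise ValueError("blocks_per_stage must be >= 1")
        divisor = 4 if self.variant == "ds" else 8
        if self.input_length % divisor or self.input_length < divisor:
            raise ValueError(
                f"input_length {self.input_length} must be a positive multiple of "
                f"{divisor} for variant {self.variant!r} (each stride-2 stage must "
                "land on an integer length)"
            )

    @property
    def stage1_kernel(self) -> int | None:
        return {"ds": None, "stage1_k3": 3, "stage1_k5": 5}[self.variant]

    @property
    def feature_width(self) -> int:
        """Channel count entering the classifier (256 at base width 16)."""
        return 16 * self.base_width

    def stage_table(self) -> list[dict]:
        """Per-stage (mid, out, kernel, stride, blocks) rows for Stages 2-4."""
        w = self.base_width
        return [
            {"name": "stage2", "mid": w, "out": 4 * w, "kernel": 3, "stride": 1,
             "blocks": self.blocks_per_stage},
            {"name": "stage3", "mid": 2 * w, "out": 8 * w, "kernel": 3, "stride": 2,
             "blocks": self.blocks_per_stage},
            {"name": "stage4", "mid": 4 * w, "out": 16 * w, "kernel": 3, "stride": 2,
             "blocks": self.blocks_per_stage},
        ]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        return cls(**d)


class PreActBottleneck:
    """Pre-activation bottleneck residual unit.

    BN -> ReLU -> 1x1 conv (stride) -> BN -> ReLU -> 1xk conv -> BN -> ReLU
    -> 1x1 conv, plus a shortcut: identity when shapes match, otherwise a
    1x1 projection convolution with matching stride applied to the
    pre-activated input.
    """

    def __init__(self, in_ch: int, mid: int, out_ch: int, kernel: int,
                 stride: int, rng: np.random.Generator, name: str):
        self.name = name
        self.bn1 = BatchNorm1d(in_ch, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv1 = Conv1d(in_ch, mid, 1, stride=stride, padding=0, rng=rng,
                            name=f"{name}.conv1")
        self.bn2 = BatchNorm1d(mid, name=f"{name}.bn2")
        self.relu2 = ReLU()
        self.conv2 = Conv1d(mid, mid, kernel, stride=1, rng=rng, name=f"{name}.conv2")
        self.bn3 = BatchNorm1d(mid, name=f"{name}.bn3")
        self.relu3 = ReLU()
        self.conv3 = Conv1d(mid, out_ch, 1, stride=1, padding=0, rng=rng,
                            name=f"{name}.conv3")
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv1d(in_ch, out_ch, 1, stride=stride, padding=0, rng=rng,
                               name=f"{name}.proj")
        else:
            self.proj = None

    def main_convs(self) -> list[Conv1d]:
        return [self.conv1, self.conv2, self.conv3]

    def params(self) -> list[Param]:
        out = []
        for layer in (self.bn1, self.conv1, self.bn2, self.conv2, self.bn3,
                      self.conv3):
            out.extend(layer.params())
        if self.proj is not None:
            out.extend(self.proj.params())
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        a = self.relu1.forward(self.bn1.forward(x, training), training)
        shortcut = x if self.proj is None else self.proj.forward(a, training)
        h = self.conv1.forward(a, training)
        h = self.relu2.forward(self.bn2.forward(h, training), training)
        h = self.conv2.forward(h, training)
        h = self.relu3.forward(self.bn3.forward(h, training), training)
        h = self.conv3.forward(h, training)
        return h + shortcut

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.conv3.backward(dy)
        dh = self.bn3.backward(self.relu3.backward(dh))
        dh = self.conv2.backward(dh)
        dh = self.bn2.backward(self.relu2.backward(dh))
        da = self.conv1.backward(dh)
        if self.proj is not None:
            da = da + self.proj.backward(dy)
            return self.bn1.backward(self.relu1.backward(da))
        return self.bn1.backward(self.relu1.backward(da)) + dy


class ResNet1D:
    """The assembled network; use :func:`build_model` to construct one."""

    def __init__(self, config: ArchitectureConfig, seed: int):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        w = config.base_width
        self.stem = Conv1d(config.input_channels, w, 5, stride=1, rng=rng,
                           name="stage0.conv")
        self.units: list[tuple[str, PreActBottleneck]] = []
        in_ch = w
        if config.variant != "ds":
            unit = PreActBottleneck(in_ch, w, w, config.stage1_kernel, stride=2,
                                    rng=rng, name="stage1.block1")
            self.units.append(("stage1", unit))
        for row in config.stage_table():
            for b in range(row["blocks"]):
                stride = row["stride"] if b == 0 else 1
                unit = PreActBottleneck(
                    in_ch, row["mid"], row["out"], row["kernel"], stride,
                    rng=rng, name=f"{row['name']}.block{b + 1}")
                self.units.append((row["name"], unit))
                in_ch = row["out"]
        self.final_bn = BatchNorm1d(in_ch, name="final.bn")
        self.final_relu = ReLU()
        self.pool = GlobalAvgPool1d()
        self.fc = Linear(in_ch, config.num_classes, rng=rng, name="classifier")

    # ---- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[1] != self.config.input_channels \
                or x.shape[2] != self.config.input_length:
            raise ValueError(
                f"expected batch of shape (n, {self.config.input_channels}, "
                f"{self.config.input_length}), got {x.shape}")
        h = self.stem.forward(x, training)
        for _, unit in self.units:
            h = unit.forward(h, training)
        h = self.final_relu.forward(self.final_bn.forward(h, training), training)
        h = self.pool.forward(h, training)
        logits = self.fc.forward(h, training)
        if not np.all(np.isfinite(logits)):
            raise FloatingPointError("non-finite logits")
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.fc.backward(dlogits)
        dh = self.pool.backward(dh)
        dh = self.final_bn.backward(self.final_relu.backward(dh))
        for _, unit in reversed(self.units):
            dh = unit.backward(dh)
        self.stem.backward(dh)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predicted class indices; ties resolve to the lowest index."""
        return np.argmax(self.forward(x, training=False), axis=1)

    # ---- introspection -------------------------------------------------
    def params(self) -> list[Param]:
        out = list(self.stem.params())
        for _, unit in self.units:
            out.extend(unit.params())
        out.extend(self.final_bn.params())
        out.extend(self.fc.params())
        return out

    def conv_entries(self):
        """Yield (stage, conv, is_projection) over every convolution."""
        yield "stage0", self.stem, False
        for stage, unit in self.units:
            for conv in unit.main_convs():
                yield stage, conv, False
            if unit.proj is not None:
                yield stage, unit.proj, True

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All model state: trainable params plus batch-norm running stats."""
        state = {f"param:{i}:{p.name}": p.value for i, p in enumerate(self.params())}
        bns = [self.final_bn]
        for _, unit in self.units:
            bns.extend([unit.bn1, unit.bn2, unit.bn3])
        for i, bn in enumerate(bns):
            state[f"buffer:{i}:{bn.name}.running_mean"] = bn.running_mean
            state[f"buffer:{i}:{bn.name}.running_var"] = bn.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        if set(own) != set(state):
            raise ValueError("checkpoint state does not match this architecture")
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"param:{i}:{p.name}"]
        bns = [self.final_bn]
        for _, unit in self.units:
            bns.extend([unit.bn1, unit.bn2, unit.bn3])
        for i, bn in enumerate(bns):
            bn.running_mean[...] = state[f"buffer:{i}:{bn.name}.running_mean"]
            bn.running_var[...] = state[f"buffer:{i}:{bn.name}.running_var"]


def build_model(config: ArchitectureConfig, seed: int = 0) -> ResNet1D:
    """Build a network with seeded He initialization (same seed, same weights)."""
    return ResNet1D(config, seed)


def forward(model: ResNet1D, batch: np.ndarray) -> np.ndarray:
    """Inference-mode forward pass returning ``(n, num_classes)`` logits."""
    return model.forward(batch, training=False)


def downsample_half(x: np.ndarray, mode: str = "subsample") -> np.ndarray:
    """Halve the temporal length of ``(..., length)`` signals.

    ``subsample`` keeps every second sample (the default reading of halving
    the signal size); ``average`` mean-pools non-overlapping pairs.
    """
    if x.shape[-1] % 2:
        raise ValueError("length must be even to halve")
    if mode == "subsample":
        return np.ascontiguousarray(x[..., ::2])
    if mode == "average":
        return 0.5 * (x[..., ::2] + x[..., 1::2])
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------

@dataclass
class LayerAccount:
    """Layer/parameter/FLOP ledger for one configuration.

    ``parameter_count`` and ``flop_count`` follow the main-path convention
    (projection shortcuts excluded); ``total_parameter_count`` is the full
    trainable total. FLOPs are for one forward pass at ``input_length``.
    """

    weighted_layer_count: int
    parameter_count: int
    total_parameter_count: int
    flop_count: int
    input_length: int
    per_stage: list[dict] = field(default_factory=list)

    def render(self) -> str:
        lines = [
            f"{'stage':<12}{'weighted layers':>16}{'params (main)':>15}"
            f"{'params (total)':>15}{'FLOPs':>14}",
        ]
        for row in self.per_stage:
            lines.append(
                f"{row['stage']:<12}{row['weighted_layers']:>16}"
                f"{row['parameters']:>15}{row['total_parameters']:>15}"
                f"{row['flops']:>14}")
        lines.append(
            f"{'total':<12}{self.weighted_layer_count:>16}"
            f"{self.parameter_count:>15}{self.total_parameter_count:>15}"
            f"{self.flop_count:>14}")
        lines.append(
            f"params {self.parameter_count / 1e6:.1f} M (main path; "
            f"{self.total_parameter_count / 1e6:.2f} M incl. projections), "
            f"FLOPs {self.flop_count / 1e6:.1f} M at input length {self.input_length}")
        return "\n".join(lines)


def count_weighted_layers(config: ArchitectureConfig) -> int:
    """Convolutional + fully connected layers, excluding projections.

    Stem (1) + Stage 1 (3 convs, Stage-1 variants only) + three main stages
    of ``blocks_per_stage`` bottlenecks of 3 convs each + classifier (1).
    """
    stage1 = 0 if config.variant == "ds" else 3
    return 1 + stage1 + 3 * config.blocks_per_stage * 3 + 1


def count_parameters(model: ResNet1D, include_projections: bool = True) -> int:
    """Total trainable scalars (convs, batch-norm scale/shift, classifier).

    With ``include_projections=False`` the projection-shortcut convolutions
    are excluded, which is the convention behind the headline figure.
    """
    total = sum(p.size for p in model.params())
    if not include_projections:
        total -= sum(conv.weight.size for _, conv, is_proj in model.conv_entries()
                     if is_proj)
    return int(total)


def count_flops(model: ResNet1D, input_length: int | None = None) -> int:
    """Forward-pass FLOPs: 2 per multiply-accumulate, main path + classifier.

    Projection shortcuts, batch norm, ReLU and pooling are excluded; this is
    the only convention consistent with the architecture's published budget.
    """
    return layer_account(model, input_length).flop_count


def layer_account(model: ResNet1D, input_length: int | None = None) -> LayerAccount:
    """Full per-stage ledger of weighted layers, parameters and FLOPs."""
    config = model.config
    if input_length is None:
        input_length = config.input_length
    if input_length != config.input_length:
        model = build_model(
            ArchitectureConfig(**{**config.to_dict(), "input_length": input_length}),
            seed=model.seed)
        config = model.config

    stage_names = ["stage0"]
    if config.variant != "ds":
        stage_names.append("stage1")
    stage_names += ["stage2", "stage3", "stage4", "head"]
    rows = {s: {"stage": s, "weighted_layers": 0, "parameters": 0,
                "total_parameters": 0, "flops": 0} for s in stage_names}

    # Convolutions: walk each unit tracking the running temporal length.
    length = config.input_length
    rows["stage0"]["weighted_layers"] = 1
    rows["stage0"]["parameters"] = model.stem.weight.size
    rows["stage0"]["total_parameters"] = model.stem.weight.size
    rows["stage0"]["flops"] = 2 * model.stem.weight.size * model.stem.out_length(length)
    length = model.stem.out_length(length)

    bn_by_stage: dict[str, int] = {s: 0 for s in stage_names}
    for stage, unit in model.units:
        lo = unit.conv1.out_length(length)
        for conv, conv_len in ((unit.conv1, lo), (unit.conv2, lo), (unit.conv3, lo)):
            rows[stage]["weighted_layers"] += 1
            rows[stage]["parameters"] += conv.weight.size
            rows[stage]["total_parameters"] += conv.weight.size
            rows[stage]["flops"] += 2 * conv.weight.size * conv_len
        if unit.proj is not None:
            rows[stage]["total_parameters"] += unit.proj.weight.size
        for bn in (unit.bn1, unit.bn2, unit.bn3):
            bn_by_stage[stage] += 2 * bn.channels
        length = lo
    for stage in bn_by_stage:
        rows[stage]["parameters"] += bn_by_stage[stage]
        rows[stage]["total_parameters"] += bn_by_stage[stage]

    head_params = (2 * model.final_bn.channels + model.fc.weight.size
                   + model.fc.bias.size)
    rows["head"]["weighted_layers"] = 1
    rows["head"]["parameters"] = head_params
    rows["head"]["total_parameters"] = head_params
    rows["head"]["flops"] = 2 * model.fc.weight.size

    per_stage = [rows[s] for s in stage_names]
    account = LayerAccount(
        weighted_layer_count=sum(r["weighted_layers"] for r in per_stage),
        parameter_count=sum(r["parameters"] for r in per_stage),
        total_parameter_count=sum(r["total_parameters"] for r in per_stage),
        flop_count=sum(r["flops"] for r in per_stage),
        input_length=config.input_length,
        per_stage=per_stage,
    )
    assert account.weighted_layer_count == count_weighted_layers(config)
    assert account.total_parameter_count == count_parameters(model)
    return account


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: ResNet1D, path) -> None:
    """Write model state plus its embedded ArchitectureConfig to ``path`` (.npz)."""
    state = model.state_arrays()
    np.savez(path, __config__=np.frombuffer(
        json.dumps({"config": model.config.to_dict(), "seed": model.seed})
        .encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> ResNet1D:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        state = {k: data[k] for k in data.files if k != "__config__"}
    model = build_model(ArchitectureConfig.from_dict(meta["config"]), meta["seed"])
    model.load_state_arrays(state)
    return model
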