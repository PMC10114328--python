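"""The revised ResNet-50 for binary diabetic-retinopathy grading.

The backbone is the standard 50-layer bottleneck residual network. The
revision taps the outputs of the first and second residual blocks of stage 5
(``conv5_block1_out`` and ``conv5_block2_out``), merges them elementwise
(multiplication by default — the merge that renders hemorrhage features most
distinctly and grades best), applies global average pooling, and classifies
with a single sigmoid unit carrying an L2 kernel penalty and an L1 activity
penalty. The third stage-5 block remains in the graph but is unused by the
head.

A ``width_multiplier`` scales every channel count so the same architecture
trains at desk scale (e.g. width 0.25 on 64x64 inputs) while width 1.0 on
224x224 inputs reproduces the full geometry (stage-5 maps of 7x7x2048).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .nn import (
    SGD,  # noqa: F401  (re-exported for training code)
    BatchNorm2d,
    Conv2d,
    Dense,
    Tensor,
    bce_with_logits,
    global_avg_pool,
    max_pool2d,
    maximum,
    relu,
    sigmoid,
    sum_abs,
    sum_squares,
)

MERGE_OPS = ("addition", "subtraction", "multiplication", "average", "maximum")

# bottleneck plan: (blocks, inner channels, output channels, stride of first block)
_STAGES = ((3, 64, 256, 1), (4, 128, 512, 2), (6, 256, 1024, 2), (3, 512, 2048, 2))


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    input_side must be divisible by 32 so the stage-5 feature maps have a
    well-defined spatial size (input_side / 32).
    """

    input_side: int = 224
    width_multiplier: float = 1.0
    n_outputs: int = 1
    init_seed: int = 0

    def __post_init__(self):
        if self.input_side % 32 != 0:
            raise ConfigError(
                f"input_side must be divisible by 32, got {self.input_side}"
            )
        if not (0 < self.width_multiplier <= 1):
            raise ConfigError("width_multiplier must be in (0, 1]")

    def width(self, c: int) -> int:
        return max(1, round(c * self.width_multiplier))


@dataclass
class FusionSpec:
    """Which stage-5 taps to merge and how."""

    merge_op: str = "multiplication"
    layer_a: str = "conv5_block1_out"
    layer_b: str = "conv5_block2_out"

    def __post_init__(self):
        if self.merge_op not in MERGE_OPS:
            raise ConfigError(
                f"unknown merge_op {self.merge_op!r}; choose from {MERGE_OPS}"
            )


@dataclass
class RegularizerSpec:
    """L2 penalty on the head kernel, L1 penalty on the head activity."""

    kernel_l2: float = 1e-4
    activity_l1: float = 1e-5

    def __post_init__(self):
        if self.kernel_l2 < 0 or self.activity_l1 < 0:
            raise ConfigError("regularizer weights must be non-negative")


def merge_features(a, b, op: str):
    """Elementwise merge of two same-shape feature tensors.

    Accepts either autodiff ``Tensor``s (graph-building, used by the model
    head) or plain numpy arrays (used by the visualization tool).
    """
    if op not in MERGE_OPS:
        raise ConfigError(f"unknown merge op {op!r}; choose from {MERGE_OPS}")
    sa = a.data.shape if isinstance(a, Tensor) else np.shape(a)
    sb = b.data.shape if isinstance(b, Tensor) else np.shape(b)
    if sa != sb:
        raise ValueError(f"merge requires identical shapes, got {sa} vs {sb}")
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        if op == "addition":
            return a + b
        if op == "subtraction":
            return a - b
        if op == "multiplication":
            return a * b
        if op == "average":
            return (a + b) * 0.5
        return maximum(a, b)
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if op == "addition":
        return a + b
    if op == "subtraction":
        return a - b
    if op == "multiplication":
        return a * b
    if op == "average":
        return (a + b) / 2.0
    return np.maximum(a, b)


def penalty(weights, activations, reg: RegularizerSpec) -> float:
    """Total regularization penalty: kernel_l2 * sum(w^2) + activity_l1 * sum(|a|)."""
    w = np.asarray(weights, dtype=np.float64)
    a = np.asarray(activations, dtype=np.float64)
    return float(reg.kernel_l2 * np.sum(w**2) + reg.activity_l1 * np.sum(np.abs(a)))


class _Bottleneck:
    """1x1 reduce -> 3x3 -> 1x1 expand with identity (or projected) shortcut."""

    def __init__(self, cin, inner, cout, stride, *, rng, params, name):
        self.conv1 = Conv2d(cin, inner, 1, rng=rng, params=params, name=f"{name}.conv1")
        self.bn1 = BatchNorm2d(inner, params=params, name=f"{name}.bn1")
        self.conv2 = Conv2d(
            inner, inner, 3, stride=stride, pad=1, rng=rng, params=params,
            name=f"{name}.conv2",
        )
        self.bn2 = BatchNorm2d(inner, params=params, name=f"{name}.bn2")
        self.conv3 = Conv2d(inner, cout, 1, rng=rng, params=params, name=f"{name}.conv3")
        # zero-init residual scale: the block starts as an identity map
        self.bn3 = BatchNorm2d(cout, params=params, name=f"{name}.bn3", gamma_init=0.0)
        if stride != 1 or cin != cout:
            self.proj = Conv2d(
                cin, cout, 1, stride=stride, rng=rng, params=params, name=f"{name}.proj"
            )
            self.bn_proj = BatchNorm2d(cout, params=params, name=f"{name}.bn_proj")
        else:
            self.proj = None

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        h = relu(self.bn1(self.conv1(x), train))
        h = relu(self.bn2(self.conv2(h), train))
        h = self.bn3(self.conv3(h), train)
        shortcut = self.bn_proj(self.proj(x), train) if self.proj is not None else x
        return relu(h + shortcut)


class ResNet50Backbone:
    """50-layer bottleneck residual network with addressable block outputs.

    Every residual block output is recorded during the forward pass under the
    name ``conv{stage}_block{n}_out`` (stages 2-5, blocks 1-based), so any
    intermediate representation can be tapped for fusion or visualization.
    """

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.params: dict[str, Tensor] = {}
        self._bn_layers: list[BatchNorm2d] = []
        rng = np.random.default_rng(cfg.init_seed)
        w = cfg.width
        self.stem_conv = Conv2d(
            3, w(64), 7, stride=2, pad=3, rng=rng, params=self.params, name="stem.conv"
        )
        self.stem_bn = BatchNorm2d(w(64), params=self.params, name="stem.bn")
        self.stages: list[list[_Bottleneck]] = []
        cin = w(64)
        for stage_idx, (blocks, inner, cout, stride) in enumerate(_STAGES, start=2):
            stage = []
            for b in range(blocks):
                stage.append(
                    _Bottleneck(
                        cin,
                        w(inner),
                        w(cout),
                        stride if b == 0 else 1,
                        rng=rng,
                        params=self.params,
                        name=f"conv{stage_idx}_block{b + 1}",
                    )
                )
                cin = w(cout)
            self.stages.append(stage)
        self.out_channels = cin
        self.layer_names = [
            f"conv{s}_block{b + 1}_out"
            for s, stage in zip(range(2, 6), self.stages)
            for b in range(len(stage))
        ]

    def forward(
        self, x: np.ndarray | Tensor, train: bool = False
    ) -> tuple[Tensor, dict[str, Tensor]]:
        """Run the backbone; returns the final stage-5 output and every
        named block activation."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        acts: dict[str, Tensor] = {}
        h = relu(self.stem_bn(self.stem_conv(x), train))
        h = max_pool2d(h, kernel=3, stride=2, pad=1)
        for stage_idx, stage in enumerate(self.stages, start=2):
            for b, block in enumerate(stage):
                h = block(h, train)
                acts[f"conv{stage_idx}_block{b + 1}_out"] = h
        return h, acts


def build_backbone(cfg: ModelConfig) -> ResNet50Backbone:
    return ResNet50Backbone(cfg)


class RevisedResNet50:
    """Backbone + elementwise stage-5 fusion + regularized sigmoid head.

    With ``fusion=None`` the head sits on the final stage-5 output
    (``conv5_block3_out``) instead — the unrevised reference model.
    """

    def __init__(
        self,
        cfg: ModelConfig,
        fusion: FusionSpec | None = FusionSpec(),
        reg: RegularizerSpec = RegularizerSpec(),
    ):
        self.cfg = cfg
        self.fusion = fusion
        self.reg = reg
        self.backbone = ResNet50Backbone(cfg)
        if fusion is not None:
            names = self.backbone.layer_names
            for layer in (fusion.layer_a, fusion.layer_b):
                if layer not in names:
                    raise ConfigError(f"unknown fusion tap {layer!r}")
        rng = np.random.default_rng(cfg.init_seed + 1)
        self.head = Dense(
            self.backbone.out_channels,
            cfg.n_outputs,
            rng=rng,
            params=self.backbone.params,
            name="head",
        )

    @property
    def params(self) -> dict[str, Tensor]:
        return self.backbone.params

    def forward(
        self, x: np.ndarray | Tensor, train: bool = False
    ) -> tuple[Tensor, dict[str, Tensor]]:
        """Returns the sigmoid probability tensor (N,1) and all activations."""
        final, acts = self.backbone.forward(x, train)
        if self.fusion is not None:
            merged = merge_features(
                acts[self.fusion.layer_a], acts[self.fusion.layer_b], self.fusion.merge_op
            )
        else:
            merged = final
        acts["merged"] = merged
        pooled = global_avg_pool(merged)
        logits = self.head(pooled)
        acts["logits"] = logits
        return sigmoid(logits), acts

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        prob, _ = self.forward(x, train=False)
        return prob.data.reshape(-1)

    def loss(self, x: np.ndarray, y: np.ndarray, train: bool = True):
        """Training objective: binary cross-entropy + kernel L2 + activity L1.

        Returns (scalar loss Tensor, probability ndarray).
        """
        final, acts = self.backbone.forward(x, train)
        if self.fusion is not None:
            merged = merge_features(
                acts[self.fusion.layer_a], acts[self.fusion.layer_b], self.fusion.merge_op
            )
        else:
            merged = final
        pooled = global_avg_pool(merged)
        logits = self.head(pooled)
        prob = sigmoid(logits)
        loss = bce_with_logits(logits, y)
        if self.reg.kernel_l2 > 0:
            loss = loss + sum_squares(self.head.weight) * self.reg.kernel_l2
        if self.reg.activity_l1 > 0:
            loss = loss + sum_abs(prob) * self.reg.activity_l1
        return loss, prob.data.reshape(-1)

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        """Checkpoint weights, batch-norm statistics, and config to .npz."""
        arrays = {f"param:{k}": p.data for k, p in self.params.items()}
        for name, bn in self._iter_bn():
            arrays[f"buffer:{name}.running_mean"] = bn.running_mean
            arrays[f"buffer:{name}.running_var"] = bn.running_var
        meta = {
            "input_side": self.cfg.input_side,
            "width_multiplier": self.cfg.width_multiplier,
            "n_outputs": self.cfg.n_outputs,
            "init_seed": self.cfg.init_seed,
            "fusion": None
            if self.fusion is None
            else [self.fusion.merge_op, self.fusion.layer_a, self.fusion.layer_b],
            "kernel_l2": self.reg.kernel_l2,
            "activity_l1": self.reg.activity_l1,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "RevisedResNet50":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg = ModelConfig(
                input_side=meta["input_side"],
                width_multiplier=meta["width_multiplier"],
                n_outputs=meta["n_outputs"],
                init_seed=meta["init_seed"],
            )
            fusion = None if meta["fusion"] is None else FusionSpec(*meta["fusion"])
            reg = RegularizerSpec(meta["kernel_l2"], meta["activity_l1"])
            model = cls(cfg, fusion, reg)
            for k, p in model.params.items():
                p.data = data[f"param:{k}"].astype(np.float32)
            for name, bn in model._iter_bn():
                bn.running_mean = data[f"buffer:{name}.running_mean"]
                bn.running_var = data[f"buffer:{name}.running_var"]
        return model

    def _iter_bn(self):
        yield "stem.bn", self.backbone.stem_bn
        for stage in self.backbone.stages:
            for block in stage:
                yield block.bn1.name, block.bn1
                yield block.bn2.name, block.bn2
                yield block.bn3.name, block.bn3
                if block.proj is not None:
                    yield block.bn_proj.name, block.bn_proj


def build_revised_model(
    cfg: ModelConfig,
    fusion: FusionSpec | None = FusionSpec(),
    reg: RegularizerSpec = RegularizerSpec(),
) -> RevisedResNet50:
    return RevisedResNet50(cfg, fusion, reg)


def images_to_batch(images) -> np.ndarray:
    """Stack HxWx3 uint8 images into an (N,3,H,W) float32 batch scaled to [0,1]."""
    arr = np.stack([np.asarray(im, dtype=np.float32) / 255.0 for im in images])
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))
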