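"""Declarative residual-network specs and their exact parameter accounting.

Three families are provided:

* ``build_dgrnet`` — the 2-D baseline: a standard 18/34/50-layer residual
  network over B-channel S x S images (B = retained principal components).
* ``build_3d_dgrnet`` — the plain 3-D analogue: single-channel B x S x S
  volumes, 7x7x7 stem, 3x3x3 block kernels, 1x1x1 projection shortcuts.
* ``build_3d_rnet_o`` — the dual-branch spectral/spatial model: every
  residual block decomposes its convolutions into a spectral kernel
  ``a x 1 x 1`` and a spatial kernel ``1 x a x a``.  Branch one applies
  spectral-then-spatial, branch two spatial-then-spectral; branch outputs are
  concatenated and fused by a 1x1x1 projection before the residual addition.

A :class:`NetworkSpec` is pure data: the exact trainable-parameter count
derives from it analytically (:func:`count_parameters`) and a trainable numpy
model derives from it with :func:`instantiate`; tests pin the two against
each other.  Convolutions carry no bias (batch norm follows every
convolution); the linear head carries weights and bias; batch-norm scale and
shift count as trainable, running statistics do not.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import nn
from .exceptions import SizeError

__all__ = [
    "StemSpec", "PoolSpec", "BlockConfig", "HeadSpec", "NetworkSpec",
    "build_dgrnet", "build_3d_dgrnet", "build_3d_rnet_o", "dual_branch_block",
    "count_parameters", "instantiate", "layer_table",
    "spec_to_yaml", "spec_from_yaml", "save_weights", "load_weights",
]

_STAGE_BLOCKS = {18: (2, 2, 2, 2), 34: (3, 4, 6, 3), 50: (3, 4, 6, 3)}
_BOTTLENECK_DEPTHS = {50}
_EXPANSION = 4


@dataclass(frozen=True)
class StemSpec:
    kernel: tuple[int, int, int]
    stride: tuple[int, int, int]
    width: int
    in_channels: int


@dataclass(frozen=True)
class PoolSpec:
    window: tuple[int, int, int]
    stride: tuple[int, int, int]


@dataclass(frozen=True)
class BlockConfig:
    """One residual block.

    kind 'basic': two ``kernel`` convolutions.
    kind 'bottleneck': 1x1 reduce to ``mid_width``, ``kernel``, 1x1 expand.
    kind 'dual': spectral/spatial branch pair with kernel scale ``a``.
    A projection shortcut (1x1x1 conv + BN) is implied whenever the stride is
    not 1 or the widths differ.
    """

    kind: str
    in_width: int
    out_width: int
    stride: tuple[int, int, int] = (1, 1, 1)
    kernel: tuple[int, int, int] = (3, 3, 3)
    mid_width: int = 0
    a: int = 3
    branch1: bool = True
    branch2: bool = True

    def __post_init__(self):
        if self.kind not in {"basic", "bottleneck", "dual"}:
            raise SizeError(f"unknown block kind {self.kind!r}")
        if self.kind == "dual" and self.a % 2 == 0:
            raise SizeError("dual-branch kernel scale a must be odd")
        if any(k % 2 == 0 for k in self.kernel):
            raise SizeError("block kernels must be odd")

    @property
    def needs_projection(self) -> bool:
        return self.stride != (1, 1, 1) or self.in_width != self.out_width


@dataclass(frozen=True)
class HeadSpec:
    in_width: int
    n_classes: int


@dataclass(frozen=True)
class NetworkSpec:
    name: str
    is3d: bool
    stem: StemSpec
    pool: PoolSpec
    stages: tuple[tuple[BlockConfig, ...], ...]
    head: HeadSpec
    # declared input contract: 3D -> (B, S, S) single-channel volume,
    # 2D -> in_channels-band S x S image
    default_input: tuple[int, ...] = (30, 9, 9)

    def __post_init__(self):
        prev = self.stem.width
        last_width = 0
        for stage in self.stages:
            for blk in stage:
                if blk.in_width != prev:
                    raise SizeError(
                        f"{self.name}: block input width {blk.in_width} does "
                        f"not chain from {prev}")
                prev = blk.out_width
                last_width = blk.out_width
        if self.head.in_width != last_width:
            raise SizeError(f"{self.name}: head width {self.head.in_width} != "
                            f"last stage width {last_width}")
        widths = [s[0].out_width for s in self.stages]
        if any(b <= 0 for b in widths) or any(
                widths[i] > widths[i + 1] for i in range(len(widths) - 1)):
            raise SizeError("stage widths must be positive and non-decreasing")

    def blocks(self):
        for si, stage in enumerate(self.stages):
            for bi, blk in enumerate(stage):
                yield si, bi, blk


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _make_stage(kind: str, in_width: int, width: int, n_blocks: int,
                stride: tuple[int, int, int], kernel, a=3,
                branch1=True, branch2=True) -> tuple[BlockConfig, ...]:
    blocks = []
    prev = in_width
    out = width * _EXPANSION if kind == "bottleneck" else width
    for i in range(n_blocks):
        s = stride if i == 0 else (1, 1, 1)
        if kind == "dual":
            blocks.append(dual_branch_block(prev, out, a, s, (branch1, branch2)))
        else:
            blocks.append(BlockConfig(kind, prev, out, s, kernel,
                                      mid_width=width if kind == "bottleneck" else 0))
        prev = out
    return tuple(blocks)


def build_dgrnet(depth: int, in_channels: int, n_classes: int = 3) -> NetworkSpec:
    """2-D residual baseline over a B-channel S x S image.

    Standard topology: 7x7/2 stem to 64 channels, 3x3/2 max pool, stage
    widths 64/128/256/512 with basic blocks (depths 18/34) or 4x-expanded
    bottlenecks (depth 50), global average pooling and a linear softmax head.
    """
    if depth not in _STAGE_BLOCKS:
        raise SizeError(f"unsupported depth {depth}; choose from 18/34/50")
    kind = "bottleneck" if depth in _BOTTLENECK_DEPTHS else "basic"
    counts = _STAGE_BLOCKS[depth]
    widths = (64, 128, 256, 512)
    stages = []
    prev = 64
    for i, (w, n) in enumerate(zip(widths, counts)):
        stride = (1, 1, 1) if i == 0 else (1, 2, 2)
        stage = _make_stage(kind, prev, w, n, stride, (1, 3, 3))
        stages.append(stage)
        prev = stage[-1].out_width
    return NetworkSpec(
        name=f"dgrnet{depth}",
        is3d=False,
        stem=StemSpec((1, 7, 7), (1, 2, 2), 64, in_channels),
        pool=PoolSpec((1, 3, 3), (1, 2, 2)),
        stages=tuple(stages),
        head=HeadSpec(prev, n_classes),
        default_input=(in_channels, 9, 9),
    )


def build_3d_dgrnet(depth: int, n_classes: int = 3,
                    default_input: tuple[int, int, int] = (30, 9, 9)) -> NetworkSpec:
    """Plain 3-D residual network on a single-channel B x S x S volume."""
    if depth not in _STAGE_BLOCKS:
        raise SizeError(f"unsupported depth {depth}; choose from 18/34/50")
    kind = "bottleneck" if depth in _BOTTLENECK_DEPTHS else "basic"
    counts = _STAGE_BLOCKS[depth]
    widths = (64, 128, 256, 512)
    stages = []
    prev = 64
    for i, (w, n) in enumerate(zip(widths, counts)):
        stride = (1, 1, 1) if i == 0 else (2, 2, 2)
        stage = _make_stage(kind, prev, w, n, stride, (3, 3, 3))
        stages.append(stage)
        prev = stage[-1].out_width
    return NetworkSpec(
        name=f"3d_dgrnet{depth}",
        is3d=True,
        stem=StemSpec((7, 7, 7), (2, 2, 2), 64, 1),
        pool=PoolSpec((3, 3, 3), (2, 2, 2)),
        stages=tuple(stages),
        head=HeadSpec(prev, n_classes),
        default_input=default_input,
    )


def dual_branch_block(in_width: int, out_width: int, a: int = 3,
                      stride: tuple[int, int, int] = (1, 1, 1),
                      branches: tuple[bool, bool] = (True, True)) -> BlockConfig:
    """Spectral/spatial dual-branch residual block configuration.

    Branch 1: conv(a,1,1) -> BN -> ReLU -> conv(1,a,a) -> BN.
    Branch 2: conv(1,a,a) -> BN -> ReLU -> conv(a,1,1) -> BN.
    Both enabled: outputs concatenated (2 * out_width) and fused by a 1x1x1
    convolution back to out_width.  One enabled: fusion is the identity.
    Neither enabled: degenerates to a plain basic block with an a x a x a
    kernel (no error; this is the ablation baseline).
    """
    if a % 2 == 0:
        raise SizeError("kernel scale a must be odd")
    b1, b2 = branches
    if not (b1 or b2):
        return BlockConfig("basic", in_width, out_width, tuple(stride), (a, a, a))
    return BlockConfig("dual", in_width, out_width, tuple(stride),
                       kernel=(a, a, a), a=a, branch1=b1, branch2=b2)


def build_3d_rnet_o(widths: tuple[int, int, int, int] = (128, 256, 512, 1024),
                    a: int = 3,
                    stem_kernel: tuple[int, int, int] = (3, 5, 5),
                    pool_window: tuple[int, int, int] = (2, 2, 2),
                    n_classes: int = 3,
                    branches: tuple[bool, bool] = (True, True),
                    depth: int = 34,
                    default_input: tuple[int, int, int] = (30, 9, 9)) -> NetworkSpec:
    """Dual-branch spectral/spatial residual network (34-layer-style backbone).

    Defaults are the optimal configuration found by the hyperparameter
    sweeps: stage widths (128, 256, 512, 1024), kernel scale a = 3, stem
    kernel (3, 5, 5) and max-pool window (2, 2, 2).
    """
    if len(widths) != 4:
        raise SizeError("exactly four stage widths required")
    if a % 2 == 0:
        raise SizeError("kernel scale a must be odd")
    counts = _STAGE_BLOCKS[depth]
    stages = []
    prev = 64
    for i, (w, n) in enumerate(zip(widths, counts)):
        stride = (1, 1, 1) if i == 0 else (2, 2, 2)
        stage = _make_stage("dual", prev, w, n, stride, (a, a, a), a=a,
                            branch1=branches[0], branch2=branches[1])
        stages.append(stage)
        prev = w
    return NetworkSpec(
        name="3d_rnet_o",
        is3d=True,
        stem=StemSpec(tuple(stem_kernel), (2, 2, 2), 64, 1),
        pool=PoolSpec(tuple(pool_window), (2, 2, 2)),
        stages=tuple(stages),
        head=HeadSpec(prev, n_classes),
        default_input=default_input,
    )


# ---------------------------------------------------------------------------
# Parameter accounting
# ---------------------------------------------------------------------------

def _conv_params(kernel, cin: int, cout: int) -> int:
    return int(np.prod(kernel)) * cin * cout


def _bn_params(c: int) -> int:
    return 2 * c


def _block_param_rows(blk: BlockConfig, prefix: str) -> list[tuple[str, str, int, int, int]]:
    """(name, kernel, in, out, params) rows for one block."""
    rows = []

    def add(name, kernel, cin, cout, bn=True):
        rows.append((f"{prefix}.{name}", "x".join(map(str, kernel)), cin, cout,
                     _conv_params(kernel, cin, cout)))
        if bn:
            rows.append((f"{prefix}.{name}.bn", "-", cout, cout, _bn_params(cout)))

    if blk.kind == "basic":
        add("conv1", blk.kernel, blk.in_width, blk.out_width)
        add("conv2", blk.kernel, blk.out_width, blk.out_width)
    elif blk.kind == "bottleneck":
        add("reduce", (1, 1, 1), blk.in_width, blk.mid_width)
        add("conv", blk.kernel, blk.mid_width, blk.mid_width)
        add("expand", (1, 1, 1), blk.mid_width, blk.out_width)
    else:  # dual
        a = blk.a
        if blk.branch1:
            add("b1.spectral", (a, 1, 1), blk.in_width, blk.out_width)
            add("b1.spatial", (1, a, a), blk.out_width, blk.out_width)
        if blk.branch2:
            add("b2.spatial", (1, a, a), blk.in_width, blk.out_width)
            add("b2.spectral", (a, 1, 1), blk.out_width, blk.out_width)
        if blk.branch1 and blk.branch2:
            add("fuse", (1, 1, 1), 2 * blk.out_width, blk.out_width)
    if blk.needs_projection:
        add("shortcut", (1, 1, 1), blk.in_width, blk.out_width)
    return rows


def block_parameters(blk: BlockConfig) -> int:
    """Trainable-parameter count of a single residual block."""
    return sum(row[4] for row in _block_param_rows(blk, "block"))


def layer_table(spec: NetworkSpec) -> pd.DataFrame:
    """Per-layer table (name, kernel, in/out widths, parameter count)."""
    rows = [("stem.conv", "x".join(map(str, spec.stem.kernel)),
             spec.stem.in_channels, spec.stem.width,
             _conv_params(spec.stem.kernel, spec.stem.in_channels, spec.stem.width)),
            ("stem.bn", "-", spec.stem.width, spec.stem.width,
             _bn_params(spec.stem.width))]
    for si, bi, blk in spec.blocks():
        rows.extend(_block_param_rows(blk, f"stage{si + 1}.block{bi + 1}"))
    rows.append(("head.linear", "-", spec.head.in_width, spec.head.n_classes,
                 spec.head.in_width * spec.head.n_classes + spec.head.n_classes))
    return pd.DataFrame(rows, columns=["name", "kernel", "in", "out", "params"])


def count_parameters(spec: NetworkSpec) -> int:
    """Exact trainable-scalar total implied by the spec.

    Counts convolution weights (no conv biases), batch-norm scale + shift,
    and the linear head's weights + bias.
    """
    return int(layer_table(spec)["params"].sum())


# ---------------------------------------------------------------------------
# Instantiation
# ---------------------------------------------------------------------------

def _build_branch(cin, cout, first_kernel, second_kernel, stride, rng, name):
    return nn.Sequential(
        nn.Conv3d(cin, cout, first_kernel, stride, rng, f"{name}.conv1"),
        nn.BatchNorm(cout, name=f"{name}.bn1"),
        nn.ReLU(),
        nn.Conv3d(cout, cout, second_kernel, 1, rng, f"{name}.conv2"),
        nn.BatchNorm(cout, name=f"{name}.bn2"),
    )


def _build_block(blk: BlockConfig, rng: np.random.Generator, name: str) -> nn.Residual:
    if blk.kind == "basic":
        main = nn.Sequential(
            nn.Conv3d(blk.in_width, blk.out_width, blk.kernel, blk.stride, rng,
                      f"{name}.conv1"),
            nn.BatchNorm(blk.out_width, name=f"{name}.bn1"),
            nn.ReLU(),
            nn.Conv3d(blk.out_width, blk.out_width, blk.kernel, 1, rng,
                      f"{name}.conv2"),
            nn.BatchNorm(blk.out_width, name=f"{name}.bn2"),
        )
    elif blk.kind == "bottleneck":
        main = nn.Sequential(
            nn.Conv3d(blk.in_width, blk.mid_width, (1, 1, 1), 1, rng,
                      f"{name}.reduce"),
            nn.BatchNorm(blk.mid_width, name=f"{name}.bn1"),
            nn.ReLU(),
            nn.Conv3d(blk.mid_width, blk.mid_width, blk.kernel, blk.stride, rng,
                      f"{name}.conv"),
            nn.BatchNorm(blk.mid_width, name=f"{name}.bn2"),
            nn.ReLU(),
            nn.Conv3d(blk.mid_width, blk.out_width, (1, 1, 1), 1, rng,
                      f"{name}.expand"),
            nn.BatchNorm(blk.out_width, name=f"{name}.bn3"),
        )
    else:  # dual
        a = blk.a
        branches = []
        if blk.branch1:
            branches.append(_build_branch(blk.in_width, blk.out_width,
                                          (a, 1, 1), (1, a, a), blk.stride,
                                          rng, f"{name}.b1"))
        if blk.branch2:
            branches.append(_build_branch(blk.in_width, blk.out_width,
                                          (1, a, a), (a, 1, 1), blk.stride,
                                          rng, f"{name}.b2"))
        if len(branches) == 2:
            main = nn.Sequential(
                nn.Parallel(*branches),
                nn.Conv3d(2 * blk.out_width, blk.out_width, (1, 1, 1), 1, rng,
                          f"{name}.fuse"),
                nn.BatchNorm(blk.out_width, name=f"{name}.bn_fuse"),
            )
        else:
            main = branches[0]
    shortcut = None
    if blk.needs_projection:
        shortcut = nn.Sequential(
            nn.Conv3d(blk.in_width, blk.out_width, (1, 1, 1), blk.stride, rng,
                      f"{name}.shortcut"),
            nn.BatchNorm(blk.out_width, name=f"{name}.shortcut_bn"),
        )
    return nn.Residual(main, shortcut)


def instantiate(spec: NetworkSpec, seed: int = 0) -> nn.Network:
    """Realize a spec as a trainable numpy network with seeded initialization."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [
        nn.Conv3d(spec.stem.in_channels, spec.stem.width, spec.stem.kernel,
                  spec.stem.stride, rng, "stem"),
        nn.BatchNorm(spec.stem.width, name="stem.bn"),
        nn.ReLU(),
        nn.MaxPool3d(spec.pool.window, spec.pool.stride),
    ]
    for si, bi, blk in spec.blocks():
        layers.append(_build_block(blk, rng, f"stage{si + 1}.block{bi + 1}"))
    layers.append(nn.GlobalAvgPool())
    layers.append(nn.Linear(spec.head.in_width, spec.head.n_classes, rng, "head"))
    in_channels = 1 if spec.is3d else spec.stem.in_channels
    return nn.Network(layers, spec.is3d, in_channels, spec.head.n_classes,
                      name=spec.name)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def spec_to_yaml(spec: NetworkSpec, path: str | None = None) -> str:
    text = yaml.safe_dump(dataclasses.asdict(spec), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _as_tuples(obj):
    if isinstance(obj, list):
        return tuple(_as_tuples(v) for v in obj)
    if isinstance(obj, dict):
        return {k: _as_tuples(v) for k, v in obj.items()}
    return obj


def save_weights(network: nn.Network, path: str) -> str:
    """Serialize trainable parameters and batch-norm statistics to .npz."""
    arrays = {}
    for i, p in enumerate(network.params()):
        arrays[f"param_{i:04d}"] = p.value
    bn_idx = 0
    for layer in _walk_layers(network):
        if isinstance(layer, nn.BatchNorm):
            arrays[f"bn_{bn_idx:04d}_mean"] = layer.running_mean
            arrays[f"bn_{bn_idx:04d}_var"] = layer.running_var
            bn_idx += 1
    np.savez_compressed(path, **arrays)
    return path


def load_weights(network: nn.Network, path: str) -> nn.Network:
    """Load parameters saved by :func:`save_weights` into a freshly built net."""
    with np.load(path) as data:
        params = network.params()
        for i, p in enumerate(params):
            stored = data[f"param_{i:04d}"]
            if stored.shape != p.value.shape:
                raise SizeError(f"checkpoint shape mismatch at param {i}: "
                                f"{stored.shape} vs {p.value.shape}")
            p.value[...] = stored
        bn_idx = 0
        for layer in _walk_layers(network):
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean = data[f"bn_{bn_idx:04d}_mean"]
                layer.running_var = data[f"bn_{bn_idx:04d}_var"]
                bn_idx += 1
    return network


def _walk_layers(layer):
    yield layer
    for attr in ("layers", "children"):
        for child in getattr(layer, attr, []):
            yield from _walk_layers(child)
    if isinstance(layer, nn.Residual):
        yield from _walk_layers(layer.main)
        if layer.shortcut is not None:
            yield from _walk_layers(layer.shortcut)


def spec_from_yaml(text_or_path: str) -> NetworkSpec:
    if "\n" not in text_or_path and text_or_path.endswith((".yml", ".yaml")):
        with open(text_or_path) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(text_or_path)
    raw = _as_tuples(raw)
    stages = tuple(tuple(BlockConfig(**dict(b)) for b in stage)
                   for stage in raw["stages"])
    return NetworkSpec(
        name=raw["name"], is3d=raw["is3d"],
        stem=StemSpec(**dict(raw["stem"])),
        pool=PoolSpec(**dict(raw["pool"])),
        stages=stages,
        head=HeadSpec(**dict(raw["head"])),
        default_input=raw.get("default_input", (30, 9, 9)),
    )
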