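"""Dual-branch multi-resolution segmentation network.

Two U-shaped branches process the same normalized CT patch:

* **Transformer branch** — a convolutional stem at full resolution, then a
  strided patch embedding followed by stages of windowed self-attention
  (regular + shifted blocks, Swin style) at successively halved resolutions,
  decoded by a convolutional decoder with skip connections.
* **Convolutional branch** — a plain U-Net: convolution blocks with
  max-pooling on the way down, nearest-neighbor upsampling with additive
  skip connections on the way up.

Each branch emits class-probability maps at several resolutions (deep
supervision); the final prediction fuses the two branches' full-resolution
maps by voxel-wise averaging.  The architecture is scale-free: the published
configuration (patch (32, 256, 256), six supervised outputs) and a tiny
desk-scale configuration (patch (16, 64, 64), base width 8) differ only in
this config object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nnet
from .nnet import Tensor

__all__ = [
    "DualModelConfig",
    "MultiResOutputs",
    "DualModel",
    "build_dual_model",
    "forward_patch",
    "fuse_final",
]


@dataclass
class DualModelConfig:
    in_channels: int = 1
    num_classes: int = 3                     # background / ICH / PHE
    patch_size: tuple[int, int, int] = (16, 64, 64)
    levels: int = 3
    base_width: int = 8
    transformer_window: tuple[int, int, int] = (2, 4, 4)
    heads_per_level: int = 2
    supervised_outputs: int | None = None    # default: min(levels + 1, 6)
    convs_per_block: int = 1
    # anisotropy-aware kernel at the finest level: clinical CT slices are much
    # thicker than pixels, so full-resolution convolutions act in-plane only
    fine_level_kernel: tuple[int, int, int] = (1, 3, 3)
    # classification-head biases start at log class priors so that extreme
    # background dominance does not collapse the lesion classes early in
    # training (lesions are well under 1% of a head CT's voxels)
    class_priors: tuple[float, ...] | None = (0.985, 0.005, 0.010)
    seed: int = 0

    def __post_init__(self):
        self.patch_size = tuple(int(p) for p in self.patch_size)
        div = 2 ** self.levels
        if any(p % div for p in self.patch_size):
            raise ValueError(
                f"patch_size {self.patch_size} must be divisible by 2^levels = {div}")
        max_outputs = self.levels + 1
        if self.supervised_outputs is None:
            self.supervised_outputs = min(max_outputs, 6)
        if not 1 <= self.supervised_outputs <= max_outputs:
            raise ValueError(
                f"supervised_outputs must be in [1, {max_outputs}]")


@dataclass
class MultiResOutputs:
    """Per-branch probability maps from full resolution downward.

    ``per_branch[b][k]`` has shape ``(B, num_classes, *patch/2^k)`` and is
    simplex-normalized per voxel.  ``prob_tensors`` retains the autodiff
    tensors for the training loss.
    """

    per_branch: list[list[np.ndarray]]
    prob_tensors: list[list[Tensor]] | None = None

    @property
    def fused(self) -> np.ndarray:
        return fuse_final(self)


def fuse_final(outs: MultiResOutputs) -> np.ndarray:
    """Voxel-wise mean of the two branches' full-resolution probability maps."""
    a, b = outs.per_branch[0][0], outs.per_branch[1][0]
    if a.shape != b.shape:
        raise ValueError(f"branch output shapes differ: {a.shape} vs {b.shape}")
    return 0.5 * (a + b)


class _ConvBlock(nnet.Module):
    """(Conv -> InstanceNorm -> LeakyReLU) x convs_per_block."""

    def __init__(self, cin, cout, rng, n_convs: int = 1, kernel=3):
        self.convs = [nnet.Conv3d(cin if i == 0 else cout, cout, kernel, rng)
                      for i in range(n_convs)]
        self.norms = [nnet.InstanceNorm3d(cout) for _ in range(n_convs)]

    def parameters(self):
        params = []
        for conv, norm in zip(self.convs, self.norms):
            params.extend(conv.parameters())
            params.extend(norm.parameters())
        return params

    def __call__(self, x):
        for conv, norm in zip(self.convs, self.norms):
            x = nnet.leaky_relu(norm(conv(x)))
        return x


class _Decoder(nnet.Module):
    """Shared decoder: upsample, 1x1 channel reduction, additive skip, conv.

    A deep-supervision head (1x1 conv to class logits) sits at the
    bottleneck and at every decoder resolution.
    """

    def __init__(self, cfg: DualModelConfig, widths, rng):
        self.levels = cfg.levels
        self.reduce = [nnet.Conv3d(widths[k + 1], widths[k], 1, rng)
                       for k in range(cfg.levels)]
        self.blocks = [_ConvBlock(widths[k], widths[k], rng, cfg.convs_per_block,
                                  kernel=cfg.fine_level_kernel if k == 0 else 3)
                       for k in range(cfg.levels)]
        self.heads = [nnet.Conv3d(widths[k], cfg.num_classes, 1, rng)
                      for k in range(cfg.levels)]
        self.bottleneck_head = nnet.Conv3d(widths[-1], cfg.num_classes, 1, rng)
        if cfg.class_priors is not None:
            if len(cfg.class_priors) != cfg.num_classes:
                raise ValueError("class_priors length must equal num_classes")
            bias = np.log(np.asarray(cfg.class_priors, dtype=np.float32))
            for head in self.heads + [self.bottleneck_head]:
                head.b.data = bias.copy()
        self.n_out = cfg.supervised_outputs

    def __call__(self, bottleneck: Tensor, skips: list[Tensor]) -> list[Tensor]:
        x = bottleneck
        logits = [self.bottleneck_head(x)]        # coarsest first, reversed below
        for k in range(self.levels - 1, -1, -1):
            x = self.reduce[k](nnet.upsample2(x)) + skips[k]
            x = self.blocks[k](x)
            logits.append(self.heads[k](x))
        logits = logits[::-1]                     # full resolution first
        return logits[:self.n_out]


class _UNetBranch(nnet.Module):
    """Convolutional encoder-decoder with max-pooling and deep supervision."""

    def __init__(self, cfg: DualModelConfig, rng):
        w = cfg.base_width
        self.levels = cfg.levels
        widths = [w * 2 ** k for k in range(cfg.levels + 1)]
        self.enc = [_ConvBlock(cfg.in_channels if k == 0 else widths[k - 1],
                               widths[k], rng, cfg.convs_per_block,
                               kernel=cfg.fine_level_kernel if k == 0 else 3)
                    for k in range(cfg.levels + 1)]
        self.decoder = _Decoder(cfg, widths, rng)

    def __call__(self, x: Tensor) -> list[Tensor]:
        skips = []
        for k in range(self.levels):
            x = self.enc[k](x)
            skips.append(x)
            x = nnet.maxpool2(x)
        x = self.enc[self.levels](x)
        return self.decoder(x, skips)


class _SwinBranch(nnet.Module):
    """Windowed self-attention encoder with a convolutional decoder.

    Stage layout: a full-resolution conv stem (the finest skip), a strided
    patch embedding to half resolution, then one regular + one shifted
    attention block per resolution down to the bottleneck.
    """

    def __init__(self, cfg: DualModelConfig, rng):
        w = cfg.base_width
        self.levels = cfg.levels
        widths = [w * 2 ** k for k in range(cfg.levels + 1)]
        self.stem = _ConvBlock(cfg.in_channels, widths[0], rng,
                               cfg.convs_per_block,
                               kernel=cfg.fine_level_kernel)
        self.embed = nnet.Conv3d(widths[0], widths[1], 3, rng, stride=2)
        self.embed_norm = nnet.InstanceNorm3d(widths[1])
        self.stages = []
        self.downs = []
        for k in range(1, cfg.levels + 1):
            blocks = [
                nnet.TransformerBlock(widths[k], cfg.heads_per_level,
                                      cfg.transformer_window, rng, shifted=False),
                nnet.TransformerBlock(widths[k], cfg.heads_per_level,
                                      cfg.transformer_window, rng, shifted=True),
            ]
            self.stages.append(blocks)
            if k < cfg.levels:
                self.downs.append(nnet.Conv3d(widths[k], widths[k + 1], 3, rng,
                                              stride=2))
        self.decoder = _Decoder(cfg, widths, rng)

    def parameters(self):
        params = super().parameters()
        for blocks in self.stages:
            for blk in blocks:
                params.extend(blk.parameters())
        return params

    def __call__(self, x: Tensor) -> list[Tensor]:
        skips = [self.stem(x)]
        x = nnet.leaky_relu(self.embed_norm(self.embed(skips[0])))
        for k in range(self.levels):
            for blk in self.stages[k]:
                x = blk(x)
            if k < self.levels - 1:
                skips.append(x)
                x = self.downs[k](x)
        return self.decoder(x, skips)


class DualModel(nnet.Module):
    """The trainable two-branch model.  Forward yields MultiResOutputs."""

    def __init__(self, cfg: DualModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.swin = _SwinBranch(cfg, rng)
        self.unet = _UNetBranch(cfg, rng)

    def parameters(self):
        return self.swin.parameters() + self.unet.parameters()

    # -- forward ----------------------------------------------------------
    def forward(self, patch: np.ndarray | Tensor) -> MultiResOutputs:
        """Run both branches on a batch ``(B, C, D, H, W)`` (or a bare patch).

        A bare ``(D, H, W)`` array is promoted to a single-sample batch.
        """
        if isinstance(patch, Tensor):
            x = patch
        else:
            arr = np.asarray(patch, dtype=np.float32)
            if arr.ndim == 3:
                arr = arr[None, None]
            elif arr.ndim == 4:
                arr = arr[:, None]
            x = Tensor(arr)
        if x.data.shape[2:] != self.cfg.patch_size:
            raise ValueError(
                f"patch shape {x.data.shape[2:]} != configured {self.cfg.patch_size}")
        prob_tensors = []
        per_branch = []
        for branch in (self.swin, self.unet):
            probs = [nnet.softmax(lg, axis=1) for lg in branch(x)]
            prob_tensors.append(probs)
            per_branch.append([p.data for p in probs])
        return MultiResOutputs(per_branch=per_branch, prob_tensors=prob_tensors)

    __call__ = forward

    def predict_probs(self, patch: np.ndarray) -> np.ndarray:
        """Fused full-resolution class probabilities, ``(C, D, H, W)``."""
        outs = self.forward(patch)
        return fuse_final(outs)[0]

    # -- weights ----------------------------------------------------------
    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state does not match model parameters")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError("parameter shape mismatch in state")
            p.data = s.copy().astype(np.float32)

    def save(self, path) -> None:
        np.savez(path, *[p.data for p in self.parameters()],
                 _config=np.array([repr(self.cfg)], dtype=object))

    @classmethod
    def load(cls, path, cfg: DualModelConfig) -> "DualModel":
        model = cls(cfg)
        with np.load(path, allow_pickle=True) as z:
            arrays = [z[f"arr_{i}"] for i in range(len(model.parameters()))]
        model.load_state_dict(arrays)
        return model


def build_dual_model(cfg: DualModelConfig) -> DualModel:
    """Construct the dual model; weight init is deterministic in cfg.seed."""
    return DualModel(cfg)


def forward_patch(model: DualModel, patch: np.ndarray) -> MultiResOutputs:
    arr = np.asarray(patch, dtype=np.float32)
    if arr.ndim == 3 and arr.shape != model.cfg.patch_size:
        raise ValueError(
            f"patch shape {arr.shape} != configured {model.cfg.patch_size}")
    return model.forward(arr)
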