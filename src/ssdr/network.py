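"""The cascaded volumetric reconstructor.

Stage 1 is a 3D U-Net operating on the low-resolution multi-view
channels; stage 2 is a second 3D U-Net at full resolution whose input is
the high-resolution channels concatenated with the (upsampled) stage-1
prediction. Before either U-Net, each back-projected view channel is
lifted to ``base_features`` feature maps by a convolution whose weights
are *shared across views*, and the per-view features are fused
elementwise (minimum by default, encoding the intersection prior of
smear back-projection) — this keeps the parameter count independent of
the number of input views.

Every U-Net level applies a double 3x3x3 convolution + ReLU block;
encoding uses factor-2 max pooling, decoding factor-2 nearest
upsampling with skip concatenation, and a final 1x1x1 convolution maps
the features to a single output channel. Channel widths double per
level starting from ``base_features``.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .containers import MultiViewInput, Volume

__all__ = [
    "UNetConfig",
    "CascadeConfig",
    "UNet3D",
    "FeatureLift",
    "CascadeModel",
    "patched_apply",
    "receptive_field_half",
]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture of one 3D U-Net.

    depth
        Number of pooling levels (clinical default 4; desk-scale tests
        use less so that tiny grids remain divisible).
    base_features
        Feature maps after the view-shared channel lift (default 16).
    kernel
        Convolution kernel edge (3 -> 3x3x3).
    """

    depth: int = 4
    base_features: int = 16
    kernel: int = 3
    fusion: str = "min"

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_features < 1:
            raise ValueError("base_features must be >= 1")
        if self.kernel % 2 == 0:
            raise ValueError("kernel must be odd")
        if self.fusion not in ("min", "mean"):
            raise ValueError("fusion must be 'min' or 'mean'")

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple(self.base_features * 2 ** l for l in range(self.depth + 1))


@dataclass(frozen=True)
class CascadeConfig:
    stage1: UNetConfig = field(default_factory=UNetConfig)
    stage2: UNetConfig = field(default_factory=UNetConfig)
    patch_z: int | None = 32


class Conv3dLayer:
    """A 3D convolution layer with He-normal initialised weights."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator):
        fan_in = cin * kernel ** 3
        std = np.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, std, (cout, cin, kernel, kernel, kernel)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv3d(x, self.w, self.b)

    @property
    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class DoubleConv:
    def __init__(self, cin, cout, kernel, rng):
        self.c1 = Conv3dLayer(cin, cout, kernel, rng)
        self.c2 = Conv3dLayer(cout, cout, kernel, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.c2(self.c1(x).relu()).relu()

    @property
    def params(self):
        return self.c1.params + self.c2.params


class UNet3D:
    """Encoder-decoder with skip connections and a 1x1x1 output head."""

    def __init__(self, in_channels: int, config: UNetConfig,
                 rng: np.random.Generator):
        self.config = config
        w = config.widths
        self.enc = []
        cin = in_channels
        for l in range(config.depth):
            self.enc.append(DoubleConv(cin, w[l], config.kernel, rng))
            cin = w[l]
        self.bottleneck = DoubleConv(cin, w[config.depth], config.kernel, rng)
        self.dec = []
        for l in reversed(range(config.depth)):
            self.dec.append(DoubleConv(w[l + 1] + w[l], w[l], config.kernel, rng))
        self.head = Conv3dLayer(w[0], 1, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        d = self.config.depth
        x, pads = _pad_to_multiple(x, 2 ** d)
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
            x = ad.maxpool2(x)
        x = self.bottleneck(x)
        for block, skip in zip(self.dec, reversed(skips)):
            x = ad.upsample2(x)
            x = block(ad.concat([skip, x]))
        x = self.head(x)
        return _crop_pads(x, pads)

    @property
    def params(self):
        out = []
        for block in self.enc:
            out += block.params
        out += self.bottleneck.params
        for block in self.dec:
            out += block.params
        out += self.head.params
        return out


def _pad_to_multiple(x: Tensor, m: int):
    pads = []
    for s in x.data.shape[1:]:
        extra = (-s) % m
        pads.append((0, extra))
    if any(p[1] for p in pads):
        x = x.pad_spatial(tuple(pads))
    return x, pads


def _crop_pads(x: Tensor, pads):
    if not any(p[1] for p in pads):
        return x
    sl = tuple(slice(0, s - p[1]) for s, p in zip(x.data.shape[1:], pads))
    return x.slice3d(sl)


class FeatureLift:
    """View-shared 1->F convolution applied to every back-projected
    channel, fused across views elementwise.

    Fusion ``min`` (default) encodes the sparse-MIP geometry prior: the
    true volume lies inside the intersection of the back-projected view
    smears, so the pointwise minimum over views is already a coarse
    reconstruction that the U-Net only has to refine. ``mean`` fusion
    is available for comparison. Either way the parameter count is
    independent of the number of views.
    """

    def __init__(self, features: int, kernel: int, rng: np.random.Generator,
                 fusion: str = "min"):
        if fusion not in ("min", "mean"):
            raise ValueError("fusion must be 'min' or 'mean'")
        self.fusion = fusion
        self.conv = Conv3dLayer(1, features, kernel, rng)
        # near-identity start: each feature initially passes the raw
        # back-projected channel through, so min-fusion begins as the
        # classical minimum-over-smears reconstruction that training
        # then refines
        c = kernel // 2
        self.conv.w.data[:, 0, c, c, c] += 1.0

    def __call__(self, channels: Tensor) -> Tensor:
        n = channels.data.shape[0]
        feats = None
        for i in range(n):
            f = self.conv(_select_channel(channels, i))
            if feats is None:
                feats = f
            elif self.fusion == "min":
                feats = ad.minimum(feats, f)
            else:
                feats = feats + f
        if self.fusion == "mean":
            feats = feats * (1.0 / n)
        return feats

    @property
    def params(self):
        return self.conv.params


def _select_channel(x: Tensor, i: int) -> Tensor:
    """Pick channel ``i`` as a 1-channel tensor (differentiable)."""
    out_data = np.ascontiguousarray(x.data[i:i + 1])
    shape = x.data.shape

    def backward(g):
        if x.requires_grad:
            gx = np.zeros(shape, dtype=np.float32)
            gx[i:i + 1] = g
            x._accum(gx)

    return Tensor._result(out_data, (x,), backward)


class CascadeModel:
    """The two-stage reconstructor (low-resolution net + refiner)."""

    def __init__(self, config: CascadeConfig | None = None, seed: int = 0):
        self.config = config or CascadeConfig()
        rng = np.random.default_rng(seed)
        c1, c2 = self.config.stage1, self.config.stage2
        self.lift1 = FeatureLift(c1.base_features, c1.kernel, rng, c1.fusion)
        self.unet1 = UNet3D(c1.base_features, c1, rng)
        self.lift2 = FeatureLift(c2.base_features, c2.kernel, rng, c2.fusion)
        self.lift2_y1 = Conv3dLayer(1, c2.base_features, c2.kernel, rng)
        # zero-conv coupling: the refiner starts identical to a
        # stage-2-only network and learns to draw on the coarse
        # reconstruction only where it helps
        self.lift2_y1.w.data[:] = 0.0
        self.unet2 = UNet3D(c2.base_features, c2, rng)

    # -- differentiable forward passes ------------------------------------
    def forward_stage1(self, channels: Tensor) -> Tensor:
        """(N, X, Y, Z) channels -> (X, Y, Z) prediction (unclamped)."""
        feats = self.lift1(channels)
        out = self.unet1(feats)
        return out.reshape(*out.data.shape[1:])

    def forward_stage2(self, channels: Tensor, y1: Tensor | None) -> Tensor:
        """High-res channels plus the (upsampled) stage-1 prediction.

        ``y1 = None`` runs the refiner without a cascade input (the
        stage-2-only ablation)."""
        feats = self.lift2(channels)
        if y1 is not None:
            if y1.data.shape != channels.data.shape[1:]:
                raise ValueError(
                    f"stage-1 prediction {y1.data.shape} does not match the "
                    f"high-resolution grid {channels.data.shape[1:]}"
                )
            feats = feats + self.lift2_y1(y1.reshape(1, *y1.data.shape))
        out = self.unet2(feats)
        return out.reshape(*out.data.shape[1:])

    # -- inference ---------------------------------------------------------
    def stage1_predict(self, input_low: MultiViewInput) -> Volume:
        """Low-resolution prediction, clamped to [0, 1]."""
        with ad.no_grad():
            pred = self.forward_stage1(Tensor(input_low.channels))
        return Volume(np.clip(pred.data, 0.0, 1.0))

    def stage2_predict(self, input_high: MultiViewInput,
                       y1: Volume | None) -> Volume:
        """Full-resolution refinement, clamped to [0, 1].

        ``y1`` must already be upsampled to the high-resolution grid
        (linear interpolation); a grid mismatch raises."""
        y1_t = None if y1 is None else Tensor(np.asarray(y1.data))
        with ad.no_grad():
            pred = self.forward_stage2(Tensor(input_high.channels), y1_t)
        return Volume(np.clip(pred.data, 0.0, 1.0))

    # -- parameters --------------------------------------------------------
    @property
    def stage1_params(self) -> list[Tensor]:
        return self.lift1.params + self.unet1.params

    @property
    def stage2_params(self) -> list[Tensor]:
        return self.lift2.params + self.lift2_y1.params + self.unet2.params

    @property
    def params(self) -> list[Tensor]:
        return self.stage1_params + self.stage2_params

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def state_dict(self) -> dict:
        return {
            "config": {
                "stage1": asdict(self.config.stage1),
                "stage2": asdict(self.config.stage2),
                "patch_z": self.config.patch_z,
            },
            "params": [p.data.copy() for p in self.params],
        }

    def load_state(self, state: dict):
        params = state["params"]
        if len(params) != len(self.params):
            raise ValueError("checkpoint does not match this architecture")
        for p, arr in zip(self.params, params):
            if p.data.shape != arr.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = arr.astype(np.float32).copy()

    def save(self, path):
        with open(path, "wb") as fh:
            pickle.dump(self.state_dict(), fh)

    @classmethod
    def load(cls, path) -> "CascadeModel":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        cfg = state["config"]
        config = CascadeConfig(
            stage1=UNetConfig(**cfg["stage1"]),
            stage2=UNetConfig(**cfg["stage2"]),
            patch_z=cfg["patch_z"],
        )
        model = cls(config)
        model.load_state(state)
        return model


def receptive_field_half(config: UNetConfig) -> int:
    """Half-width (voxels) of the U-Net receptive field along any axis.

    Recursively: the bottleneck double conv spreads ``2r`` (r = kernel
    // 2); wrapping one level adds an encoder and a decoder double conv
    (``4r``) and doubles the inner spread through the pool/upsample
    pair, plus two voxels of pooling-window growth (floor/ceil
    asymmetry): ``H(l) = 2 H(l-1) + 4r + 2``.
    """
    r = config.kernel // 2
    half = 2 * r
    for _ in range(config.depth):
        half = 2 * half + 4 * r + 2
    return half


def patched_apply(fn, channels: np.ndarray, patch_z: int,
                  multiple: int = 1) -> np.ndarray:
    """Apply ``fn`` to Z-slabs of ``channels`` and restitch.

    ``channels`` is ``(N, X, Y, Z)``; slabs are full X-Y cross-sections
    of thickness ``patch_z`` (the last slab is zero-padded to size and
    the output cropped back). ``fn`` maps a channel slab to a
    ``(X, Y, z)`` volume. ``multiple`` asserts divisibility needed by
    the network (``2**depth``).
    """
    patch_z = int(patch_z)
    if patch_z < 1:
        raise ValueError("patch_z must be >= 1")
    if patch_z % multiple:
        raise ValueError(
            f"patch_z={patch_z} is not divisible by the required factor {multiple}"
        )
    nz = channels.shape[-1]
    outs = []
    for z0 in range(0, nz, patch_z):
        slab = channels[..., z0:z0 + patch_z]
        true_z = slab.shape[-1]
        if true_z < patch_z:
            pad = [(0, 0)] * (channels.ndim - 1) + [(0, patch_z - true_z)]
            slab = np.pad(slab, pad)
        out = fn(slab)
        outs.append(out[..., :true_z])
    return np.concatenate(outs, axis=-1)
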