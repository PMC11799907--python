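"""Full network assembly, configuration presets and checkpointing.

Architecture (reference configuration):

    stem 3x3 conv -> [DyC-IS block + 2x2 max pool] x3        (to 1/8 scale)
    semantic branch: [DyC-IS block + pool] x2                (to 1/32 scale)
    spatial branch:  3x3 conv at 1/8 scale
    fusion: mutual sigmoid gating (FEM) + concat + 1x1 merge (at 1/8)
    decoder: [PFF-DyC block] x3 with skips from encoder stages 3, 2, 1
    head: dynamic 3x3 convolution to 1 channel + sigmoid

The stage widths shipped as the reference configuration were frozen by
searching width ladders with the analytic profiler against the published
complexity budget of LightAWNet (2.83 M parameters at K = 4; see
docs/methods.md for the calibration procedure).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .autodiff import (BatchNorm2d, Conv2d, Module, Tensor, gelu, sigmoid)
from .decoder import PFFBlock, PFFSpec, UPSAMPLE_MODES
from .dynconv import DynConv2d, DynConvSpec
from .encoder import DyCISBlock, DyCISSpec, downsample
from .fusion import BranchPair, FusionModule

CONV_MODES = ("dynamic", "static", "static_2x")

#: stem, encoder 1-3, semantic 1-2, spatial, decoder entry, decoder 1-3
REFERENCE_WIDTHS = (8, 16, 44, 56, 128, 392, 88, 128, 32, 16, 8)

WIDTH_NAMES = ("stem", "enc1", "enc2", "enc3", "sem1", "sem2",
               "spatial", "merge", "dec1", "dec2", "dec3")


@dataclass(frozen=True)
class NetworkConfig:
    """Every architectural degree of freedom, including ablation toggles."""

    in_channels: int = 1
    stage_widths: tuple = REFERENCE_WIDTHS
    K: int = 4
    dyconv_kernel: int = 3
    dw_kernel: int = 7
    expansion: int = 4
    se_enabled: bool = True
    fem_enabled: bool = True
    se_reduction: int = 4
    upsample_mode: str = "channel_then_size"
    trans_kernel: int = 4
    conv_mode: str = "dynamic"
    threshold: float = 0.5

    def __post_init__(self):
        if self.conv_mode not in CONV_MODES:
            raise ValueError(f"unknown conv_mode {self.conv_mode!r}")
        if self.upsample_mode not in UPSAMPLE_MODES:
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")
        if len(self.stage_widths) != len(WIDTH_NAMES):
            raise ValueError(
                f"stage_widths needs {len(WIDTH_NAMES)} entries "
                f"({', '.join(WIDTH_NAMES)}); got {len(self.stage_widths)}")
        for name, w in zip(WIDTH_NAMES, self.stage_widths):
            if w < 1:
                raise ValueError(f"stage {name!r} has non-positive width {w}")
        for name in ("merge", "dec1", "dec2"):
            w = self.effective_widths()[WIDTH_NAMES.index(name)]
            if w % 2:
                raise ValueError(
                    f"stage {name!r} width {w} must be even (decoder halving)")

    def effective_widths(self) -> tuple:
        """Stage widths after applying the conv-mode doubling rule."""
        if self.conv_mode == "static_2x":
            return tuple(2 * w for w in self.stage_widths)
        return tuple(self.stage_widths)

    @property
    def dynamic(self) -> bool:
        return self.conv_mode == "dynamic"

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_widths"] = list(self.stage_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if "stage_widths" in d:
            d["stage_widths"] = tuple(d["stage_widths"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc.get("network", doc))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"network": self.to_dict()}, fh, sort_keys=False)


#: ablation presets mirroring the published variant table rows
PRESETS: dict[str, NetworkConfig] = {
    "reference": NetworkConfig(),
    "table7_conv": NetworkConfig(conv_mode="static"),
    "table7_conv2x": NetworkConfig(conv_mode="static_2x"),
    "table8_base": NetworkConfig(se_enabled=False, fem_enabled=False),
    "table8_base_se": NetworkConfig(se_enabled=True, fem_enabled=False),
    "table8_base_fem": NetworkConfig(se_enabled=False, fem_enabled=True),
    "table9_trans": NetworkConfig(upsample_mode="transposed"),
    "table9_size_first": NetworkConfig(upsample_mode="size_then_channel"),
}


def get_preset(name: str) -> NetworkConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{', '.join(sorted(PRESETS))}") from None


class LightAWNet(Module):
    """Encoder-decoder segmentation network with dynamic convolutions."""

    def __init__(self, config: NetworkConfig, *, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        w = config.effective_widths()
        (stem, e1, e2, e3, s1, s2, sp, m0, d1, d2, d3) = w
        dyn = config.dynamic
        K = config.K

        def dycis(ci, co):
            return DyCISBlock(DyCISSpec(
                ci, co, dw_kernel=config.dw_kernel,
                expansion=config.expansion,
                dyconv_kernel=config.dyconv_kernel, K=K), rng=rng,
                dynamic=dyn)

        self.stem = Conv2d(config.in_channels, stem, 3, rng=rng)
        self.stem_bn = BatchNorm2d(stem)
        self.enc = [dycis(stem, e1), dycis(e1, e2), dycis(e2, e3)]
        self.sem = [dycis(e3, s1), dycis(s1, s2)]
        self.spatial = Conv2d(e3, sp, 3, rng=rng)
        self.spatial_bn = BatchNorm2d(sp)
        self.fusion = FusionModule(s2, sp, m0,
                                   fem_enabled=config.fem_enabled, rng=rng)

        def pff(ci, cs, co):
            return PFFBlock(PFFSpec(
                ci, cs, co, upsample_mode=config.upsample_mode,
                se_enabled=config.se_enabled,
                se_reduction=config.se_reduction,
                dyconv_kernel=config.dyconv_kernel, K=K,
                trans_kernel=config.trans_kernel), rng=rng, dynamic=dyn)

        self.dec = [pff(m0, e3, d1), pff(d1, e2, d2), pff(d2, e1, d3)]
        self.head = DynConv2d(DynConvSpec(d3, 1, k=config.dyconv_kernel, K=K),
                              rng=rng, dynamic=dyn)

    def forward(self, x: Tensor) -> Tensor:
        """Probability map in (0, 1), same H x W as the input."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        B, C, H, W = x.shape
        if C != self.config.in_channels:
            raise ValueError(
                f"input has {C} channels, network expects "
                f"{self.config.in_channels}")
        if H % 32 or W % 32:
            raise ValueError(
                f"input {H}x{W} not divisible by 32; resize upstream")
        h = gelu(self.stem_bn(self.stem(x)))
        skips = []
        for block in self.enc:
            h = block(h)
            skips.append(h)          # pre-pool stage output
            h = downsample(h)
        # h is now at 1/8 scale
        sp = gelu(self.spatial_bn(self.spatial(h)))
        sem = h
        for block in self.sem:
            sem = downsample(block(sem))
        h = self.fusion(BranchPair(semantic=sem, spatial=sp))
        for block, skip in zip(self.dec, reversed(skips)):
            h = block(h, skip)
        return sigmoid(self.head(h))


def build(config: NetworkConfig, *, seed: int = 0) -> LightAWNet:
    """Instantiate a network with deterministic, seeded initialization."""
    return LightAWNet(config, seed=seed)


def predict_mask(probs: np.ndarray | Tensor,
                 threshold: float = 0.5) -> np.ndarray:
    """Binarize a probability map: mask = probs >= threshold (uint8)."""
    if isinstance(probs, Tensor):
        probs = probs.data
    return (np.asarray(probs) >= threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# Checkpoints: one .npz archive holding every array plus a config snapshot
# ---------------------------------------------------------------------------


def state_dict(net: LightAWNet) -> dict[str, np.ndarray]:
    state = {f"param/{k}": p.data for k, p in net.named_parameters()}
    for name, mod in net.named_modules():
        if isinstance(mod, BatchNorm2d):
            state[f"buffer/{name}.running_mean"] = mod.running_mean
            state[f"buffer/{name}.running_var"] = mod.running_var
    return state


def load_state_dict(net: LightAWNet, state: dict[str, np.ndarray]) -> None:
    params = dict(net.named_parameters())
    for key, arr in state.items():
        kind, _, name = key.partition("/")
        if kind == "param":
            if name not in params:
                raise KeyError(f"unexpected parameter {name!r} in checkpoint")
            if params[name].data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name!r}")
            params[name].data = arr.astype(np.float32).copy()
        elif kind == "buffer":
            mod_name, _, buf = name.rpartition(".")
            mod = dict(net.named_modules())[mod_name]
            setattr(mod, buf, arr.astype(np.float32).copy())


def save_checkpoint(path, net: LightAWNet, *, epoch: int = 0,
                    optimizer_state: dict | None = None) -> None:
    arrays = state_dict(net)
    meta = {"config": net.config.to_dict(), "epoch": epoch}
    if optimizer_state is not None:
        for i, (m, v) in enumerate(zip(optimizer_state["m"],
                                       optimizer_state["v"])):
            arrays[f"opt/m{i}"] = m
            arrays[f"opt/v{i}"] = v
        meta["opt_t"] = optimizer_state["t"]
    arrays["meta"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[LightAWNet, dict]:
    with np.load(path) as archive:
        arrays = {k: archive[k] for k in archive.files}
    meta = json.loads(bytes(arrays.pop("meta")).decode())
    config = NetworkConfig.from_dict(meta["config"])
    net = build(config)
    state = {k: v for k, v in arrays.items() if not k.startswith("opt/")}
    load_state_dict(net, state)
    return net, meta


def write_preset_yamls(directory) -> None:
    """Write every named preset as a YAML config file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, cfg in PRESETS.items():
        cfg.to_yaml(directory / f"{name}.yaml")
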