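"""Analytic parameter and MAC accounting for any network configuration.

Parameter counts enumerate every trainable scalar (kernel banks x K,
attention affines, batch-norm scales/shifts, SE affines, biases) in closed
form, without instantiating the network. MACs follow the fused multiply-add
convention used by lightweight-network papers: one MAC per kernel tap per
output element for convolutions (structural zeros of transposed convolutions
excluded), with the attention affine, bank-fusion and SE affines counted as
well; interpolation, pooling, normalisation, activations and elementwise
gates are pure data movement or pointwise work and count zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import WIDTH_NAMES, NetworkConfig


@dataclass
class ComplexityReport:
    """Totals plus a per-module breakdown (name, params, macs)."""

    param_count: int
    mac_count: int
    rows: list = field(default_factory=list)
    input_hw: tuple | None = None

    @property
    def params_m(self) -> float:
        return round(self.param_count / 1e6, 2)

    @property
    def gflops(self) -> float:
        return round(self.mac_count / 1e9, 2)

    def as_tsv(self) -> str:
        lines = ["module\tparams\tmacs"]
        for name, p, m in self.rows:
            lines.append(f"{name}\t{p}\t{m}")
        lines.append(f"TOTAL\t{self.param_count}\t{self.mac_count}")
        return "\n".join(lines)


def _dyn_layer(cin: int, cout: int, k: int, K: int, dynamic: bool):
    """(params, per-forward overhead MACs) of one (dynamic) conv layer."""
    bank = k * k * cin * cout + cout
    if dynamic:
        return K * bank + cin * K + K, cin * K + K * bank
    return bank, 0


def _profile(config: NetworkConfig, H: int | None, W: int | None):
    w = dict(zip(WIDTH_NAMES, config.effective_widths()))
    dyn = config.dynamic
    K, dk = config.K, config.dyconv_kernel
    dw = config.dw_kernel
    e = config.expansion
    rows = []

    if H is None:
        p1 = p2 = p4 = p8 = p16 = 0
    else:
        p1 = H * W
        p2, p4, p8, p16 = p1 // 4, p1 // 16, p1 // 64, p1 // 256

    def add(name, params, macs):
        rows.append((name, int(params), int(macs)))

    cin = config.in_channels
    add("stem.conv", 9 * cin * w["stem"] + w["stem"],
        9 * cin * w["stem"] * p1)
    add("stem.bn", 2 * w["stem"], 0)

    def dycis(name, a, b, px):
        add(f"{name}.dw", dw * dw * a + a, dw * dw * a * px)
        add(f"{name}.c1", e * a * a + e * a, e * a * a * px)
        add(f"{name}.bn1", 2 * e * a, 0)
        add(f"{name}.c2", e * a + 1, e * a * px)
        add(f"{name}.c3", 2 * e * a * a + a, 2 * e * a * a * px)
        add(f"{name}.bn3", 2 * a, 0)
        dp, dm = _dyn_layer(a, b, dk, K, dyn)
        add(f"{name}.dyconv", dp, dk * dk * a * b * px + dm)

    dycis("enc1", w["stem"], w["enc1"], p1)
    dycis("enc2", w["enc1"], w["enc2"], p2)
    dycis("enc3", w["enc2"], w["enc3"], p4)
    dycis("sem1", w["enc3"], w["sem1"], p8)
    dycis("sem2", w["sem1"], w["sem2"], p16)

    add("spatial.conv", 9 * w["enc3"] * w["spatial"] + w["spatial"],
        9 * w["enc3"] * w["spatial"] * p8)
    add("spatial.bn", 2 * w["spatial"], 0)

    if config.fem_enabled:
        add("fusion.gate.adapt_sem",
            w["sem2"] * w["spatial"] + w["spatial"],
            w["sem2"] * w["spatial"] * p8)
        add("fusion.gate.adapt_sp",
            w["spatial"] * w["sem2"] + w["sem2"],
            w["spatial"] * w["sem2"] * p8)
    add("fusion.merge",
        (w["sem2"] + w["spatial"]) * w["merge"] + w["merge"],
        (w["sem2"] + w["spatial"]) * w["merge"] * p8)
    add("fusion.merge.bn", 2 * w["merge"], 0)

    def pff(name, ci, cs, co, pin, pout):
        c2 = ci // 2
        if config.upsample_mode == "transposed":
            kt = config.trans_kernel
            add(f"{name}.up", kt * kt * ci * c2 + c2,
                kt * kt * ci * c2 * pout // 4)
        elif config.upsample_mode == "size_then_channel":
            add(f"{name}.up", ci * c2 + c2, ci * c2 * pout)
        else:
            add(f"{name}.up", ci * c2 + c2, ci * c2 * pin)
        if config.se_enabled:
            r = config.se_reduction
            add(f"{name}.se", c2 * (c2 // r) * 2 + c2 // r + c2,
                c2 * (c2 // r) * 2)
        dp, dm = _dyn_layer(c2 + cs, co, dk, K, dyn)
        add(f"{name}.dyconv", dp, dk * dk * (c2 + cs) * co * pout + dm)
        add(f"{name}.bn", 2 * co, 0)

    pff("dec1", w["merge"], w["enc3"], w["dec1"], p8, p4)
    pff("dec2", w["dec1"], w["enc2"], w["dec2"], p4, p2)
    pff("dec3", w["dec2"], w["enc1"], w["dec3"], p2, p1)

    hp, hm = _dyn_layer(w["dec3"], 1, dk, K, dyn)
    add("head.dyconv", hp, dk * dk * w["dec3"] * 1 * p1 + hm)

    return rows


def count_params(config: NetworkConfig) -> ComplexityReport:
    """Exact trainable-parameter count for a configuration."""
    rows = _profile(config, None, None)
    total = sum(p for _, p, _ in rows)
    return ComplexityReport(param_count=total, mac_count=0, rows=rows)


def count_macs(config: NetworkConfig, H: int, W: int) -> ComplexityReport:
    """Exact MAC count for one forward pass on a single H x W input."""
    if H % 32 or W % 32:
        raise ValueError(f"input {H}x{W} not divisible by 32")
    rows = _profile(config, H, W)
    return ComplexityReport(param_count=sum(p for _, p, _ in rows),
                            mac_count=sum(m for _, _, m in rows),
                            rows=rows, input_hw=(H, W))


def profile(config: NetworkConfig, H: int, W: int) -> ComplexityReport:
    """Parameters and MACs in one report."""
    return count_macs(config, H, W)
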