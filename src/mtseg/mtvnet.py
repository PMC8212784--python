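"""Multi-task V-Net: shared encoder with multi-depth fusion blocks and two
parallel decoders.

The encoder alternates convolution, a multi-depth fusion block, and a
strided-convolution downsampling at each level (filters doubling).  Two
structurally identical decoders restore resolution with transposed
convolutions and skip connections from the matching encoder level: the
mask decoder ends in a softmax over the 4 label channels, the distance
decoder in a sigmoid over the 3 foreground channels, whose output
regresses the normalized interior distance maps and regularizes the
mask boundary during joint training.

The multi-depth fusion block averages feature signals that have passed
through different numbers of 3×3×3 convolutions and adds the block
input back as a residual:

    F(x)  = ½ · (conv(conv(x)) + conv(x))
    y     = x + ½ · (F₂(F₁(x)) + conv(x))

where each conv is a (convolution, batch-norm, ReLU) unit with its own
weights and the two fusion stages F₁, F₂ are independent.  Input and
output resolution and channel count are identical, so the block drops
in before every downsampling layer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import Adam, Conv3d, ConvUnit, sigmoid, softmax

__all__ = ["NetworkConfig", "MultiDepthFusionBlock", "MultiTaskVNet", "build_network"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``num_classes`` is the mask-head channel count (background + 3 tumor
    classes) and ``distance_channels`` must equal ``num_classes - 1``:
    the distance decoder regresses one map per foreground class.
    """

    input_channels: int = 4
    num_classes: int = 4
    distance_channels: int = 3
    encoder_levels: int = 4
    base_filters: int = 16
    normalization: str = "batch"  # "batch", "instance", or "none"
    fusion: bool = True  # Model I ablation: fusion=False
    seed: int = 0

    def validate(self) -> None:
        if self.distance_channels != self.num_classes - 1:
            raise ValueError(
                f"distance_channels ({self.distance_channels}) must equal num_classes - 1 "
                f"({self.num_classes - 1})"
            )
        if self.encoder_levels < 2:
            raise ValueError("encoder_levels must be >= 2")
        if self.base_filters < 1 or self.input_channels < 1:
            raise ValueError("base_filters and input_channels must be positive")
        if self.normalization not in ("batch", "instance", "none"):
            raise ValueError("normalization must be 'batch', 'instance' or 'none'")

    @property
    def divisor(self) -> int:
        return 2 ** (self.encoder_levels - 1)


class MultiDepthFusionBlock:
    """Channel- and shape-preserving fusion of multi-depth feature signals."""

    def __init__(self, channels: int, norm: bool = True, rng: np.random.Generator | None = None):
        self.channels = channels
        mk = lambda: ConvUnit(channels, channels, kernel=3, norm=norm, rng=rng)
        # F1 uses u1,u2 (two-conv path) and u3 (one-conv path); F2 uses u4..u6;
        # u7 is the single convolution averaged with F2(F1(x)).
        self.units = [mk() for _ in range(7)]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(f"fusion block expects {self.channels} channels, got {x.shape[1]}")
        u = self.units
        f1 = 0.5 * (u[1].forward(u[0].forward(x, training), training) + u[2].forward(x, training))
        f2 = 0.5 * (u[4].forward(u[3].forward(f1, training), training) + u[5].forward(f1, training))
        return x + 0.5 * (f2 + u[6].forward(x, training))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        u = self.units
        gx = gy.copy()  # residual path
        gx += u[6].backward(0.5 * gy)
        g_f2 = 0.5 * gy
        g_f1 = u[5].backward(0.5 * g_f2)
        g_f1 += u[3].backward(u[4].backward(0.5 * g_f2))
        gx += u[2].backward(0.5 * g_f1)
        gx += u[0].backward(u[1].backward(0.5 * g_f1))
        return gx

    def named_params(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, unit in enumerate(self.units):
            out |= unit.named_params(f"{prefix}u{i}.")
        return out

    def named_grads(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, unit in enumerate(self.units):
            out |= unit.named_grads(f"{prefix}u{i}.")
        return out


class _Decoder:
    """One upsampling path: per level a transposed conv, skip concat, conv."""

    def __init__(self, filters: list[int], out_channels: int, norm: bool, rng: np.random.Generator):
        self.ups: list[ConvUnit] = []
        self.merges: list[ConvUnit] = []
        # filters, e.g. [16, 32, 64]; walk from the deepest level upwards
        for lvl in range(len(filters) - 1, 0, -1):
            self.ups.append(ConvUnit(filters[lvl], filters[lvl - 1], kernel=2, norm=norm, rng=rng, transpose=True))
            self.merges.append(ConvUnit(2 * filters[lvl - 1], filters[lvl - 1], kernel=3, norm=norm, rng=rng))
        self.head = Conv3d(filters[0], out_channels, kernel=1, rng=rng)

    def forward(self, x: np.ndarray, skips: list[np.ndarray], training: bool) -> np.ndarray:
        for up, merge, skip in zip(self.ups, self.merges, reversed(skips)):
            x = up.forward(x, training)
            x = np.concatenate([skip, x], axis=1)
            x = merge.forward(x, training)
        return self.head.forward(x, training)

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Return the bottom-feature gradient and per-level skip gradients.

        ``skip_grads[lvl]`` matches encoder level ``lvl`` (shallowest
        first), i.e. the order the skips were produced in the encoder.
        """
        g = self.head.backward(gy)
        skip_grads: list[np.ndarray] = []
        # reverse of forward: shallowest (last-applied) stage first
        for i in range(len(self.ups) - 1, -1, -1):
            g = self.merges[i].backward(g)
            c = g.shape[1] // 2
            skip_grads.append(g[:, :c])
            g = self.ups[i].backward(g[:, c:])
        return g, skip_grads  # already shallowest-level first

    def named_params(self, prefix: str) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, (up, merge) in enumerate(zip(self.ups, self.merges)):
            out |= up.named_params(f"{prefix}up{i}.")
            out |= merge.named_params(f"{prefix}merge{i}.")
        out |= self.head.named_params(f"{prefix}head.")
        return out

    def named_grads(self, prefix: str) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, (up, merge) in enumerate(zip(self.ups, self.merges)):
            out |= up.named_grads(f"{prefix}up{i}.")
            out |= merge.named_grads(f"{prefix}merge{i}.")
        out |= {f"{prefix}head.{k}": v for k, v in self.head.grads.items()}
        return out


class MultiTaskVNet:
    """The full dual-decoder network with explicit forward/backward passes."""

    def __init__(self, config: NetworkConfig | None = None):
        self.config = config = config or NetworkConfig()
        config.validate()
        rng = np.random.default_rng(config.seed)
        norm = None if config.normalization == "none" else config.normalization
        L = config.encoder_levels
        self.filters = [config.base_filters * 2**lvl for lvl in range(L)]

        self.stem = ConvUnit(config.input_channels, self.filters[0], norm=norm, rng=rng)
        self.enc_convs: list[ConvUnit] = []
        self.fusions: list[MultiDepthFusionBlock | None] = []
        self.downs: list[ConvUnit] = []
        for lvl in range(L - 1):
            f = self.filters[lvl]
            self.enc_convs.append(ConvUnit(f, f, norm=norm, rng=rng))
            self.fusions.append(MultiDepthFusionBlock(f, norm=norm, rng=rng) if config.fusion else None)
            self.downs.append(ConvUnit(f, self.filters[lvl + 1], kernel=2, stride=2, norm=norm, rng=rng))
        fb = self.filters[-1]
        self.bottom = [ConvUnit(fb, fb, norm=norm, rng=rng), ConvUnit(fb, fb, norm=norm, rng=rng)]
        self.mask_decoder = _Decoder(self.filters, config.num_classes, norm, rng)
        self.dist_decoder = _Decoder(self.filters, config.distance_channels, norm, rng)
        self._cache: dict | None = None

    # ---------------------------------------------------------------- forward
    def forward(self, x: np.ndarray, training: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Run a (N, 4, D, H, W) patch through both heads.

        Returns softmax mask probabilities (N, 4, D, H, W) and sigmoid
        distance predictions (N, 3, D, H, W) at the input resolution.
        """
        d = self.config.divisor
        if any(s % d for s in x.shape[2:]):
            raise ValueError(
                f"spatial shape {x.shape[2:]} must be divisible by 2^(encoder_levels-1) = {d}"
            )
        h = self.stem.forward(x, training)
        skips: list[np.ndarray] = []
        for conv, fusion, down in zip(self.enc_convs, self.fusions, self.downs):
            h = conv.forward(h, training)
            if fusion is not None:
                h = fusion.forward(h, training)
            skips.append(h)
            h = down.forward(h, training)
        for unit in self.bottom:
            h = unit.forward(h, training)
        mask_logits = self.mask_decoder.forward(h, skips, training)
        dist_logits = self.dist_decoder.forward(h, skips, training)
        mask_probs = softmax(mask_logits, axis=1)
        dist_pred = sigmoid(dist_logits)
        if training:
            self._cache = {"mask_probs": mask_probs, "dist_pred": dist_pred}
        return mask_probs, dist_pred

    # --------------------------------------------------------------- backward
    def backward(self, g_mask_probs: np.ndarray, g_dist_pred: np.ndarray) -> None:
        """Backpropagate gradients given w.r.t. the two head outputs."""
        p = self._cache["mask_probs"]
        s = self._cache["dist_pred"]
        # softmax jacobian: dL/dz = p * (g - sum_c g*p)
        g_mask = p * (g_mask_probs - (g_mask_probs * p).sum(axis=1, keepdims=True))
        g_dist = g_dist_pred * s * (1.0 - s)

        g_bottom_m, skip_g_m = self.mask_decoder.backward(g_mask)
        g_bottom_d, skip_g_d = self.dist_decoder.backward(g_dist)
        g = g_bottom_m + g_bottom_d
        for unit in reversed(self.bottom):
            g = unit.backward(g)
        for lvl in range(len(self.downs) - 1, -1, -1):
            g = self.downs[lvl].backward(g)
            g = g + skip_g_m[lvl] + skip_g_d[lvl]
            if self.fusions[lvl] is not None:
                g = self.fusions[lvl].backward(g)
            g = self.enc_convs[lvl].backward(g)
        self.stem.backward(g)

    # -------------------------------------------------------------- parameters
    def named_params(self) -> dict[str, np.ndarray]:
        out = self.stem.named_params("stem.")
        for lvl, (conv, fusion, down) in enumerate(zip(self.enc_convs, self.fusions, self.downs)):
            out |= conv.named_params(f"enc{lvl}.conv.")
            if fusion is not None:
                out |= fusion.named_params(f"enc{lvl}.fusion.")
            out |= down.named_params(f"enc{lvl}.down.")
        for i, unit in enumerate(self.bottom):
            out |= unit.named_params(f"bottom{i}.")
        out |= self.mask_decoder.named_params("mask_dec.")
        out |= self.dist_decoder.named_params("dist_dec.")
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out = self.stem.named_grads("stem.")
        for lvl, (conv, fusion, down) in enumerate(zip(self.enc_convs, self.fusions, self.downs)):
            out |= conv.named_grads(f"enc{lvl}.conv.")
            if fusion is not None:
                out |= fusion.named_grads(f"enc{lvl}.fusion.")
            out |= down.named_grads(f"enc{lvl}.down.")
        for i, unit in enumerate(self.bottom):
            out |= unit.named_grads(f"bottom{i}.")
        out |= self.mask_decoder.named_grads("mask_dec.")
        out |= self.dist_decoder.named_grads("dist_dec.")
        return out

    def n_parameters(self) -> int:
        return sum(int(v.size) for v in self.named_params().values())

    def make_optimizer(self, **kw) -> Adam:
        return Adam(self.named_params(), **kw)

    # -------------------------------------------------------------- checkpoint
    def _bn_stats(self) -> dict[str, np.ndarray]:
        stats: dict[str, np.ndarray] = {}

        from .nn import BatchNorm3d

        def visit(prefix: str, unit) -> None:
            if isinstance(unit, ConvUnit) and isinstance(unit.bn, BatchNorm3d):
                stats[prefix + "running_mean"] = unit.bn.running_mean
                stats[prefix + "running_var"] = unit.bn.running_var

        visit("stem.", self.stem)
        for lvl, (conv, fusion, down) in enumerate(zip(self.enc_convs, self.fusions, self.downs)):
            visit(f"enc{lvl}.conv.", conv)
            if fusion is not None:
                for i, u in enumerate(fusion.units):
                    visit(f"enc{lvl}.fusion.u{i}.", u)
            visit(f"enc{lvl}.down.", down)
        for i, unit in enumerate(self.bottom):
            visit(f"bottom{i}.", unit)
        for name, dec in (("mask_dec.", self.mask_decoder), ("dist_dec.", self.dist_decoder)):
            for i, (up, merge) in enumerate(zip(dec.ups, dec.merges)):
                visit(f"{name}up{i}.", up)
                visit(f"{name}merge{i}.", merge)
        return stats

    def save(self, path: str | Path) -> None:
        """Checkpoint weights + batch-norm running stats (.npz) and config (.json)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"param:{k}": v for k, v in self.named_params().items()}
        arrays |= {f"stat:{k}": v for k, v in self._bn_stats().items()}
        np.savez(path, **arrays)
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MultiTaskVNet":
        path = Path(path)
        config = NetworkConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(config)
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
            params = model.named_params()
            stats = model._bn_stats()
            for key in data.files:
                kind, name = key.split(":", 1)
                target = params if kind == "param" else stats
                target[name][...] = data[key]
        return model


def build_network(config: NetworkConfig | None = None) -> MultiTaskVNet:
    """Construct the multi-task network from a :class:`NetworkConfig`."""
    return MultiTaskVNet(config)
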