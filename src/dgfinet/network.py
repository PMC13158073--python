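"""Dual-branch guided feature interaction network (DGFI-Net) assembly.

The model is two parallel U-shaped encoder-decoders.  The main branch encodes
with context-refinement blocks (ECRB) and carries the segmentation head; the
auxiliary branch encodes with attention-guided refinement blocks (AGFRB) and
guides the main branch twice:

* during encoding, each auxiliary stage output is adapted by a 1x1 conv and
  added to the corresponding main stage output before pooling;
* during decoding, the auxiliary decoder's full-resolution feature map is
  average-pooled by factors 1, 2 and 4 and fused into the three shallowest
  main-decoder levels (elementwise sum through a 1x1 adapter by default, or
  concatenation followed by a 1x1 conv).

The main bottleneck may be reinforced by a lightweight reinforcement module
(LRM).  Four boolean flags switch each component, spanning the ablation
ladder from a plain double-conv U-Net baseline to the full model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import autodiff as ad
from . import nn
from .blocks import AGFRB, ECRB, LRM, DoubleConv

ABLATION_VARIANTS = {
    "baseline": dict(use_ecrb=False, use_agfrb=False, use_dgfi=False, use_lrm=False),
    "ecrb": dict(use_ecrb=True, use_agfrb=False, use_dgfi=False, use_lrm=False),
    "agfrb": dict(use_ecrb=False, use_agfrb=True, use_dgfi=False, use_lrm=False),
    "ecrb_agfrb_dgfi": dict(use_ecrb=True, use_agfrb=True, use_dgfi=True,
                            use_lrm=False),
    "full": dict(use_ecrb=True, use_agfrb=True, use_dgfi=True, use_lrm=True),
}


@dataclass
class ModelConfig:
    """Every architectural hyper-parameter left open by the design.

    ``stage_widths`` are the encoder channel widths (one per stage);
    ``lrm_layers``/``lrm_kernel`` are the bottleneck reinforcement depth L and
    depthwise kernel extent k; the four ``use_*`` flags select the ablation
    components.
    """

    in_channels: int = 1
    num_stages: int = 4
    stage_widths: list[int] = field(default_factory=lambda: [32, 64, 128, 256])
    bottleneck_width: int = 512
    lrm_layers: int = 2
    lrm_kernel: int = 3
    ecrb_dilation: int = 2
    eca_gamma: int = 2
    eca_b: int = 1
    eca_kernel: int | None = None
    fusion_mode: str = "sum"
    upsample_mode: str = "bilinear"
    use_ecrb: bool = False
    use_agfrb: bool = False
    use_dgfi: bool = False
    use_lrm: bool = False

    def __post_init__(self):
        if len(self.stage_widths) != self.num_stages:
            raise ValueError(
                f"stage_widths has {len(self.stage_widths)} entries for "
                f"{self.num_stages} stages"
            )
        if any(w < 1 for w in self.stage_widths) or self.bottleneck_width < 1:
            raise ValueError("all widths must be >= 1")
        if self.lrm_kernel % 2 == 0:
            raise ValueError(f"lrm_kernel must be odd, got {self.lrm_kernel}")
        if self.lrm_layers < 1:
            raise ValueError(f"lrm_layers must be >= 1, got {self.lrm_layers}")
        if self.fusion_mode not in ("sum", "concat"):
            raise ValueError(f"fusion_mode must be 'sum' or 'concat', "
                             f"got {self.fusion_mode!r}")
        if self.upsample_mode not in ("bilinear", "transposed"):
            raise ValueError(f"upsample_mode must be 'bilinear' or "
                             f"'transposed', got {self.upsample_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def ablation_variant(name: str, base: ModelConfig | None = None) -> ModelConfig:
    """Config for one rung of the ablation ladder.

    ``baseline`` (plain U-Net), ``ecrb``, ``agfrb`` (single-branch AGFRB
    encoder), ``ecrb_agfrb_dgfi`` (dual branch without bottleneck
    reinforcement) and ``full``.
    """
    if name not in ABLATION_VARIANTS:
        raise ValueError(
            f"unknown variant {name!r}; valid names: "
            f"{', '.join(ABLATION_VARIANTS)}"
        )
    d = (base.to_dict() if base is not None else ModelConfig().to_dict())
    d.update(ABLATION_VARIANTS[name])
    return ModelConfig.from_dict(d)


class _Up(nn.Module):
    """2x upsampling into a new channel width.

    ``bilinear``: fixed bilinear interpolation followed by a 1x1 conv+BN+ReLU;
    ``transposed``: learned 2x2 stride-2 transposed conv + BN + ReLU.
    """

    def __init__(self, rng, in_channels, out_channels, mode):
        super().__init__()
        self.mode = mode
        if mode == "bilinear":
            self.conv = nn.ConvBNReLU(rng, in_channels, out_channels, 1)
        else:
            self.tconv = nn.ConvTranspose2d2x(rng, in_channels, out_channels,
                                              bias=False)
            self.bn = nn.BatchNorm2d(out_channels)

    def forward(self, x):
        if self.mode == "bilinear":
            return self.conv(ad.upsample_bilinear_2x(x))
        return ad.relu(self.bn(self.tconv(x)))


def _encoder_stages(rng, cfg: ModelConfig, kind: str) -> nn.Sequential:
    stages = []
    chans = [cfg.in_channels] + list(cfg.stage_widths)
    for cin, cout in zip(chans[:-1], chans[1:]):
        if kind == "ecrb":
            stages.append(ECRB(rng, cin, cout, cfg.ecrb_dilation))
        elif kind == "agfrb":
            stages.append(AGFRB(rng, cin, cout, cfg.eca_gamma, cfg.eca_b,
                                cfg.eca_kernel))
        else:
            stages.append(DoubleConv(rng, cin, cout))
    return nn.Sequential(*stages)


def _decoder(rng, cfg: ModelConfig):
    """(up modules, conv modules), ordered deep -> shallow level index."""
    ups, convs = [], []
    widths = list(cfg.stage_widths)
    above = [cfg.bottleneck_width] + widths[:0:-1]  # incoming channel widths
    for d, src in zip(range(cfg.num_stages - 1, -1, -1), above):
        ups.append(_Up(rng, src, widths[d], cfg.upsample_mode))
        convs.append(DoubleConv(rng, 2 * widths[d], widths[d]))
    return nn.Sequential(*ups), nn.Sequential(*convs)


class DGFINet(nn.Module):
    """The assembled model; build through :func:`build_model` for seeding."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        S = cfg.num_stages
        widths = list(cfg.stage_widths)

        if cfg.use_ecrb:
            main_kind = "ecrb"
        elif cfg.use_agfrb and not cfg.use_dgfi:
            main_kind = "agfrb"  # standalone single-branch AGFRB encoder
        else:
            main_kind = "plain"
        self.encoder = _encoder_stages(rng, cfg, main_kind)
        self.bottleneck = DoubleConv(rng, widths[-1], cfg.bottleneck_width)
        if cfg.use_lrm:
            self.lrm = LRM(rng, cfg.bottleneck_width, cfg.lrm_layers,
                           cfg.lrm_kernel)
        self.decoder_up, self.decoder_conv = _decoder(rng, cfg)

        if cfg.use_dgfi:
            aux_kind = "agfrb" if cfg.use_agfrb else "plain"
            self.aux_encoder = _encoder_stages(rng, cfg, aux_kind)
            self.aux_bottleneck = DoubleConv(rng, widths[-1],
                                             cfg.bottleneck_width)
            self.aux_decoder_up, self.aux_decoder_conv = _decoder(rng, cfg)
            # encoder guidance: 1x1 adaptation of each aux stage output
            self.guide = nn.Sequential(*[
                nn.Conv2d(rng, w, w, 1) for w in widths
            ])
            # decoder guidance: aux full-resolution map pooled by 1, 2, 4
            n_fuse = min(3, S)
            if cfg.fusion_mode == "sum":
                self.fuse = nn.Sequential(*[
                    nn.Conv2d(rng, widths[0], widths[d], 1)
                    for d in range(n_fuse)
                ])
            else:
                self.fuse = nn.Sequential(*[
                    nn.ConvBNReLU(rng, widths[d] + widths[0], widths[d], 1)
                    for d in range(n_fuse)
                ])
        self.head = nn.Conv2d(rng, widths[0], 1, 1, bias=True)

    # ------------------------------------------------------------------
    def _check_input(self, x):
        H, W = x.shape[2], x.shape[3]
        mult = 2 ** self.cfg.num_stages
        if H % mult or W % mult:
            raise ValueError(
                f"input spatial extent {H}x{W} must be a multiple of {mult} "
                f"(2^num_stages)"
            )
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, "
                f"got {x.shape[1]}"
            )

    def _run_branch(self, x, stages, bottleneck, guide_feats=None):
        """One encoder-decoder sweep; returns (decoder levels, skips)."""
        skips = []
        h = x
        for s, stage in enumerate(stages.layers):
            h = stage(h)
            if guide_feats is not None:
                h = h + self.guide.layers[s](guide_feats[s])
            skips.append(h)
            h = ad.max_pool2d(h)
        h = bottleneck(h)
        return h, skips

    def forward(self, x):
        if not isinstance(x, ad.Tensor):
            x = ad.Tensor(np.asarray(x, dtype=nn.DTYPE))
        self._check_input(x)
        cfg = self.cfg
        S = cfg.num_stages

        aux_full = None
        aux_skips = None
        if cfg.use_dgfi:
            h, aux_skips = self._run_branch(x, self.aux_encoder,
                                            self.aux_bottleneck)
            for i, d in enumerate(range(S - 1, -1, -1)):
                h = self.aux_decoder_up.layers[i](h)
                h = self.aux_decoder_conv.layers[i](
                    ad.concat([h, aux_skips[d]], axis=1)
                )
            aux_full = h  # [B, stage_widths[0], H, W]

        h, skips = self._run_branch(x, self.encoder, self.bottleneck,
                                    guide_feats=aux_skips)
        if cfg.use_lrm:
            h = self.lrm(h)
        n_fuse = min(3, S) if cfg.use_dgfi else 0
        for i, d in enumerate(range(S - 1, -1, -1)):
            h = self.decoder_up.layers[i](h)
            h = self.decoder_conv.layers[i](ad.concat([h, skips[d]], axis=1))
            if aux_full is not None and d < n_fuse:
                pooled = ad.avg_pool2d(aux_full, 2**d)
                if cfg.fusion_mode == "sum":
                    h = h + self.fuse.layers[d](pooled)
                else:
                    h = self.fuse.layers[d](ad.concat([h, pooled], axis=1))
        # clamp logits so float32 sigmoid stays strictly inside (0, 1)
        return ad.sigmoid(ad.clip(self.head(h), -15.0, 15.0))

    def predict(self, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Inference without graph recording; returns probabilities."""
        was_training = self.training
        self.eval()
        outs = []
        with ad.no_grad():
            for i in range(0, images.shape[0], batch_size):
                outs.append(self(images[i : i + batch_size]).data)
        if was_training:
            self.train()
        return np.concatenate(outs, axis=0)


def build_model(cfg: ModelConfig, seed: int = 0) -> DGFINet:
    """Deterministic construction: same (cfg, seed) -> identical parameters."""
    model = DGFINet(cfg, np.random.default_rng(seed))
    model.seed = seed
    return model


def count_parameters(model: DGFINet) -> int:
    return int(sum(p.size for _, p in model.named_parameters()))


def count_mult_adds(model: DGFINet, input_size) -> int:
    """Analytic multiply-add count of all convolutions at ``input_size``.

    ``input_size`` is a side length or an (H, W) pair; the count is for a
    single image (batch 1).  Normalization, pooling and activations are not
    counted, per the usual convention for convolutional mult-add totals.
    """
    if np.isscalar(input_size):
        input_size = (int(input_size), int(input_size))
    H, W = input_size
    x = np.zeros((1, model.cfg.in_channels, H, W), dtype=nn.DTYPE)
    was_training = model.training
    model.eval()
    ad._mac_counter = [0]
    try:
        with ad.no_grad():
            model(x)
        total = int(ad._mac_counter[0])
    finally:
        ad._mac_counter = None
        if was_training:
            model.train()
    return total


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: DGFINet, path):
    """Single-archive checkpoint: config echo, seed and the named registry."""
    arrays = {"param/" + k: p.data for k, p in model.named_parameters()}
    arrays.update({"buffer/" + k: b for k, b in model.named_buffers()})
    meta = json.dumps(
        {"config": model.cfg.to_dict(), "seed": int(getattr(model, "seed", 0))}
    )
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)


def load_checkpoint(path) -> DGFINet:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        model = build_model(ModelConfig.from_dict(meta["config"]), meta["seed"])
        params = dict(model.named_parameters())
        buffers = dict(model.named_buffers())
        for key in z.files:
            if key.startswith("param/"):
                params[key[6:]].data = z[key].copy()
            elif key.startswith("buffer/"):
                buffers[key[7:]][...] = z[key]
    return model


def get_state(model: DGFINet) -> dict[str, np.ndarray]:
    state = {"param/" + k: p.data.copy() for k, p in model.named_parameters()}
    state.update({"buffer/" + k: b.copy() for k, b in model.named_buffers()})
    return state


def set_state(model: DGFINet, state: dict[str, np.ndarray]):
    params = dict(model.named_parameters())
    buffers = dict(model.named_buffers())
    for key, arr in state.items():
        if key.startswith("param/"):
            params[key[6:]].data = arr.copy()
        elif key.startswith("buffer/"):
            buffers[key[7:]][...] = arr
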