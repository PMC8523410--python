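"""Network variants: segmentation-only, classification-only, and the joint
shared-encoder two-branch network.

All three are convolution/batch-norm/ReLU stacks built from the NumPy
layers in :mod:`usjoint.nn`:

* the **encoder** down-samples with 2x2 max pooling after each
  conv-BN-ReLU stage;
* the **segmentation decoder** restores full resolution with fixed
  bilinear interpolation only (no learned transposed convolutions),
  merging encoder features back in through 1x1 projections (additive
  skips) so fine spatial detail survives the bottleneck;
* the **classification branch** global-average-pools the deepest shared
  feature map and applies fully connected layers ending in class logits;
* the **classification-only** variant is a VGG-style conv stack with
  batch normalization on a lesion-centred patch, reduced to the desk
  profile's widths.

The ``desk`` profile (encoder widths 16/32/64/128, two FC hidden layers)
keeps the joint network under 2M parameters so it trains in minutes on a
single CPU; the ``clinical`` profile widens everything 4x for users who want
a closer-to-production graph.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize

from . import nn
from .interaction import ClickSet, encode_input, tight_box
from .phantom import LesionRecord

VARIANTS = ("seg_only", "cls_only", "joint")

#: hard ceiling on the desk profile's size — keeps CPU training tractable
DESK_MAX_PARAMS = 2_000_000

#: probability threshold turning the foreground map into a binary mask
SEG_THRESHOLD = 0.5

#: input side for the classification-only variant after patch resampling
CLS_PATCH_SIZE = 64


@dataclass(frozen=True)
class NetworkConfig:
    variant: str = "joint"
    n_classes: int = 4
    encoder_widths: tuple[int, ...] = (16, 32, 64, 128)
    fc_widths: tuple[int, ...] = (64, 32)
    profile: str = "desk"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.n_classes not in (2, 4):
            raise ValueError("n_classes must be 2 or 4")
        if len(self.encoder_widths) < 2:
            raise ValueError("need encoder_depth >= 2")
        widths = tuple(self.encoder_widths)
        if self.profile == "clinical":
            widths = tuple(4 * w for w in widths)
        object.__setattr__(self, "encoder_widths", widths)

    @property
    def encoder_depth(self) -> int:
        return len(self.encoder_widths)

    @property
    def input_channels(self) -> int:
        return 1 if self.variant == "cls_only" else 3


@dataclass
class JointPrediction:
    """Per-pixel foreground probabilities plus a class probability vector."""

    seg_prob: np.ndarray | None  # (H, W) in [0, 1], None for cls_only
    cls_prob: np.ndarray | None  # (K,) summing to 1, None for seg_only

    @property
    def seg_mask(self) -> np.ndarray:
        if self.seg_prob is None:
            raise ValueError("no segmentation branch in this variant")
        return self.seg_prob >= SEG_THRESHOLD

    @property
    def predicted_class(self) -> int:
        if self.cls_prob is None:
            raise ValueError("no classification branch in this variant")
        return int(np.argmax(self.cls_prob))


class _ConvBNReLU(nn.Sequential):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__(nn.Conv2d(cin, cout, 3, rng), nn.BatchNorm2d(cout), nn.ReLU())


class EncoderDecoderNet:
    """Shared encoder + bilinear decoder + optional classification branch.

    Covers the ``seg_only`` (no class head) and ``joint`` variants.
    """

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        w = config.encoder_widths
        cin = config.input_channels
        self.enc_stages = [_ConvBNReLU(c0, c1, rng)
                           for c0, c1 in zip((cin,) + w[:-1], w)]
        self.pools = [nn.MaxPool2x2() for _ in w]
        # decoder mirrors the encoder at half width, deep -> shallow
        dec_w = [max(w[i] // 2, 8) for i in range(len(w) - 1, -1, -1)]
        self.ups = [nn.BilinearUp2x() for _ in dec_w]
        self.dec_convs = []
        self.skip_projs = []
        c_prev = w[-1]
        for i, cw in enumerate(dec_w):
            self.dec_convs.append(nn.Conv2d(c_prev, cw, 3, rng))
            skip_width = w[len(w) - 1 - i]
            self.skip_projs.append(nn.Conv2d(skip_width, cw, 1, rng))
            c_prev = cw
        self.dec_bnrelu = [nn.Sequential(nn.BatchNorm2d(cw), nn.ReLU()) for cw in dec_w]
        self.seg_head = nn.Conv2d(dec_w[-1], 1, 1, rng)
        self.gap = nn.GlobalAvgPool()
        if config.variant == "joint":
            dims = (w[-1],) + tuple(config.fc_widths)
            hidden: list[nn.Layer] = []
            for d0, d1 in zip(dims[:-1], dims[1:]):
                hidden += [nn.Linear(d0, d1, rng), nn.BatchNorm1d(d1), nn.LeakyReLU()]
            self.fc_stack = nn.Sequential(*hidden)
            self.cls_head = nn.Linear(dims[-1], config.n_classes, rng)
        else:
            self.fc_stack, self.cls_head = nn.Sequential(), None

    # -- plumbing ----------------------------------------------------------
    def params(self) -> list[nn.Param]:
        out = []
        for st in self.enc_stages:
            out += st.params()
        for cv, pj, br in zip(self.dec_convs, self.skip_projs, self.dec_bnrelu):
            out += cv.params() + pj.params() + br.params()
        out += self.seg_head.params()
        out += self.fc_stack.params()
        if self.cls_head is not None:
            out += self.cls_head.params()
        return out

    def check_input(self, x: np.ndarray) -> None:
        div = 2 ** self.config.encoder_depth
        h, w = x.shape[-2:]
        if h % div or w % div:
            raise ValueError(
                f"spatial size ({h}, {w}) must be divisible by 2^depth = {div}")

    def forward(self, x: np.ndarray, train: bool = True
                ) -> tuple[np.ndarray, np.ndarray | None]:
        """Returns (seg logits (N, H, W), cls logits (N, K) or None)."""
        self.check_input(x)
        feats = []
        h = np.ascontiguousarray(x, dtype=nn.DTYPE)
        for st, pool in zip(self.enc_stages, self.pools):
            f = st.forward(h, train)
            feats.append(f)
            h = pool.forward(f, train)
        deepest = h
        for up, cv, pj, br, skip in zip(self.ups, self.dec_convs, self.skip_projs,
                                        self.dec_bnrelu, feats[::-1]):
            h = cv.forward(up.forward(h, train), train) + pj.forward(skip, train)
            h = br.forward(h, train)
        seg_logit = self.seg_head.forward(h, train)[:, 0]
        cls_logit = None
        if self.cls_head is not None:
            v = self.fc_stack.forward(self.gap.forward(deepest, train), train)
            cls_logit = self.cls_head.forward(v, train)
        return seg_logit, cls_logit

    def backward(self, g_seg: np.ndarray, g_cls: np.ndarray | None) -> None:
        g = self.seg_head.backward(g_seg[:, None].astype(nn.DTYPE))
        g_skips = []
        for up, cv, pj, br in zip(self.ups[::-1], self.dec_convs[::-1],
                                  self.skip_projs[::-1], self.dec_bnrelu[::-1]):
            g = br.backward(g)
            g_skips.append(pj.backward(g))
            g = up.backward(cv.backward(g))
        # g now reaches the deepest pooled features; add the class-branch grad
        if self.cls_head is not None and g_cls is not None:
            gv = self.fc_stack.backward(self.cls_head.backward(g_cls.astype(nn.DTYPE)))
            g = g + self.gap.backward(gv)
        # walk back up the encoder, merging the skip gradients (shallow last)
        g_skips = g_skips[::-1]  # now ordered deep->shallow like enc_stages[::-1]
        for st, pool, gs in zip(self.enc_stages[::-1], self.pools[::-1], g_skips):
            g = st.backward(pool.backward(g) + gs)


class VGGClassifier:
    """Classification-only variant: VGG-style conv stack with batch
    normalization on a 1-channel lesion patch, desk-reduced widths."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        layers: list[nn.Layer] = []
        cin = 1
        for width in config.encoder_widths:
            layers += [_ConvBNReLU(cin, width, rng), nn.MaxPool2x2()]
            cin = width
        self.conv = nn.Sequential(*layers)
        self.gap = nn.GlobalAvgPool()
        dims = (config.encoder_widths[-1],) + tuple(config.fc_widths)
        fcl: list[nn.Layer] = []
        for d0, d1 in zip(dims[:-1], dims[1:]):
            fcl += [nn.Linear(d0, d1, rng), nn.BatchNorm1d(d1), nn.LeakyReLU()]
        fcl.append(nn.Linear(dims[-1], config.n_classes, rng))
        self.fc = nn.Sequential(*fcl)

    def params(self) -> list[nn.Param]:
        return self.conv.params() + self.fc.params()

    def check_input(self, x: np.ndarray) -> None:
        div = 2 ** self.config.encoder_depth
        h, w = x.shape[-2:]
        if h % div or w % div:
            raise ValueError(
                f"spatial size ({h}, {w}) must be divisible by 2^depth = {div}")

    def forward(self, x: np.ndarray, train: bool = True
                ) -> tuple[None, np.ndarray]:
        self.check_input(x)
        h = self.conv.forward(np.ascontiguousarray(x, dtype=nn.DTYPE), train)
        return None, self.fc.forward(self.gap.forward(h, train), train)

    def backward(self, g_seg: None, g_cls: np.ndarray) -> None:
        g = self.fc.backward(g_cls.astype(nn.DTYPE))
        self.conv.backward(self.gap.backward(g))


def build_network(config: NetworkConfig, rng_seed: int = 0):
    """Instantiate a network variant with seeded He-style initialization.

    (Initialization from a network pretrained on breast-ultrasound images
    is not reproducible without those weights; seeded random initialization
    is used instead, optionally warm-started by pretraining on phantoms via
    the training module.)
    """
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 314159]))
    if config.variant == "cls_only":
        net = VGGClassifier(config, rng)
    else:
        net = EncoderDecoderNet(config, rng)
    if config.profile == "desk":
        n = parameter_count(net)
        if n >= DESK_MAX_PARAMS:
            raise ValueError(f"desk profile must stay under {DESK_MAX_PARAMS} "
                             f"parameters, got {n}")
    return net


def parameter_count(net) -> int:
    return int(sum(p.value.size for p in net.params()))


def predict(net, encoded: np.ndarray) -> JointPrediction:
    """Inference on one encoded input (3, H, W) or patch (1, H, W).

    Deterministic: batch-norm uses running statistics.
    """
    x = np.asarray(encoded, dtype=nn.DTYPE)
    if x.ndim != 3:
        raise ValueError("expected a single (C, H, W) input")
    seg_logit, cls_logit = net.forward(x[None], train=False)
    seg_prob = nn.sigmoid(seg_logit[0]) if seg_logit is not None else None
    cls_prob = nn.softmax(cls_logit[0]) if cls_logit is not None else None
    return JointPrediction(seg_prob=seg_prob, cls_prob=cls_prob)


def predict_batch(net, encoded: np.ndarray) -> list[JointPrediction]:
    """Inference on a batch (N, C, H, W); one JointPrediction per item."""
    x = np.asarray(encoded, dtype=nn.DTYPE)
    seg_logit, cls_logit = net.forward(x, train=False)
    out = []
    for i in range(x.shape[0]):
        seg = nn.sigmoid(seg_logit[i]) if seg_logit is not None else None
        cls = nn.softmax(cls_logit[i]) if cls_logit is not None else None
        out.append(JointPrediction(seg_prob=seg, cls_prob=cls))
    return out


def patch_bounds(box) -> tuple[int, int, int]:
    """(r0, c0, side) of the lesion-centred patch: a square centred on the
    tight-box centre with side twice the longer box side."""
    cr = (box.top + box.bottom) / 2.0
    cc = (box.left + box.right) / 2.0
    side = 2 * max(box.bottom - box.top + 1, box.right - box.left + 1)
    return int(np.floor(cr - side / 2.0)), int(np.floor(cc - side / 2.0)), side


def extract_patch(record: LesionRecord, mask_or_box=None,
                  out_size: int = CLS_PATCH_SIZE) -> np.ndarray:
    """Lesion-centred square patch, side = twice the lesion's tight-box
    longer side, edge-replicated at image borders, resampled to
    ``out_size`` and scaled to [0, 1].  Input to the cls_only variant."""
    if mask_or_box is None:
        mask_or_box = record.mask
    if isinstance(mask_or_box, np.ndarray):
        box = tight_box(mask_or_box)
    else:
        box = mask_or_box
    h, w = record.image.shape
    r0, c0, side = patch_bounds(box)
    r1, c1 = r0 + side, c0 + side
    pad_t, pad_l = max(0, -r0), max(0, -c0)
    pad_b, pad_r = max(0, r1 - h), max(0, c1 - w)
    img = np.pad(record.image, ((pad_t, pad_b), (pad_l, pad_r)), mode="edge")
    patch = img[r0 + pad_t : r1 + pad_t, c0 + pad_l : c1 + pad_l]
    out = resize(patch.astype(np.float64) / 255.0, (out_size, out_size),
                 order=1, mode="edge", anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)


def encode_record(record: LesionRecord, clicks: ClickSet) -> np.ndarray:
    """Convenience: encode a phantom record with a click set."""
    return encode_input(record.image, clicks)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(net, config: NetworkConfig, path: str | Path) -> None:
    state = {
        "config": asdict(config),
        "params": [p.value for p in net.params()],
        "bn_stats": _bn_stats(net),
    }
    with open(path, "wb") as f:
        pickle.dump(state, f)


def load_checkpoint(path: str | Path):
    with open(path, "rb") as f:
        state = pickle.load(f)
    cfg_d = dict(state["config"])
    cfg_d["encoder_widths"] = tuple(cfg_d["encoder_widths"])
    cfg_d["fc_widths"] = tuple(cfg_d["fc_widths"])
    if cfg_d.get("profile") == "clinical":  # widths already expanded when saved
        cfg_d["encoder_widths"] = tuple(w // 4 for w in cfg_d["encoder_widths"])
    config = NetworkConfig(**cfg_d)
    net = build_network(config)
    for p, v in zip(net.params(), state["params"]):
        p.value[...] = v
    for bn, (rm, rv) in zip(_bn_layers(net), state["bn_stats"]):
        bn.running_mean[...] = rm
        bn.running_var[...] = rv
    return net, config


def _bn_layers(net) -> list[nn.BatchNorm2d]:
    found = []

    def walk(obj):
        if isinstance(obj, (nn.BatchNorm2d, nn.BatchNorm1d)):
            found.append(obj)
        elif isinstance(obj, nn.Sequential):
            for l in obj.layers:
                walk(l)

    for attr in ("enc_stages", "dec_bnrelu", "conv", "fc_stack", "fc"):
        sub = getattr(net, attr, None)
        if sub is None:
            continue
        if isinstance(sub, list):
            for s in sub:
                walk(s)
        else:
            walk(sub)
    return found


def _bn_stats(net) -> list[tuple[np.ndarray, np.ndarray]]:
    return [(bn.running_mean.copy(), bn.running_var.copy()) for bn in _bn_layers(net)]
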