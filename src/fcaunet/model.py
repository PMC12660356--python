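"""The FCAU-Net architecture and its building blocks.

FCAU-Net is an attention-gated U-Net for ovarian-ultrasound
classification with a Feature Fusion Context (FFC) module at the
bottleneck.  The FFC module combines dual attention (channel attention
over the Gram matrix of channel-flattened features, position attention
over pairwise pixel affinities) with a two-scale convolutional fusion:
the bottleneck map and a quarter-scale companion are each processed by
position/context blocks, multiplied pairwise, and recombined as
``FM_OS_Out + 4 * Upsample(FM_SS_Out)``.

Ablation switches on :class:`ModelConfig` reconstruct the variant
lattice from plain U-Net (no FFC module, skip connections passed by
concatenation) up to the full model (FFC module plus the modified
attention gate with batch norm and dropout).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .nn import engine as E
from .nn.engine import Tensor
from .types import LABELS, LabeledSample

__all__ = [
    "ConvSpec",
    "ModelConfig",
    "TrainParams",
    "conv2d",
    "sigmoid",
    "channel_attention",
    "position_attention",
    "attention_gate",
    "ffc_fuse",
    "FCAUNet",
    "build_fcau_net",
    "train_model",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------
# functional feature-map operations (C x H x W numpy arrays)
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class ConvSpec:
    """Kernel weights plus stride/padding/depthwise flags for :func:`conv2d`."""

    kernel: np.ndarray
    stride: int = 1
    padding: Optional[int] = None  # None: 'same' for odd kernels
    depthwise: bool = False

    def __post_init__(self):
        k = np.asarray(self.kernel)
        ksize = k.shape[-1]
        if self.padding is None and ksize % 2 == 0:
            raise ValueError("'same' padding requires an odd kernel size")


def _fm(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"feature map must be C x H x W, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("feature map entries must be finite")
    return arr


def conv2d(fm: np.ndarray, spec: ConvSpec) -> np.ndarray:
    """Discrete cross-correlation of a C x H x W map with a kernel stack."""
    x = _fm(fm)[None]
    k = np.asarray(spec.kernel, dtype=np.float64)
    pad = spec.padding if spec.padding is not None else k.shape[-1] // 2
    if spec.depthwise:
        if k.ndim != 3 or k.shape[0] != x.shape[1]:
            raise ValueError("depthwise kernel must be (C, kh, kw) matching channels")
        out = E.depthwise_conv2d(Tensor(x), Tensor(k), stride=spec.stride, pad=pad)
    else:
        if k.ndim != 4 or k.shape[1] != x.shape[1]:
            raise ValueError("kernel must be (Cout, Cin, kh, kw) matching channels")
        out = E.conv2d(Tensor(x), Tensor(k), stride=spec.stride, pad=pad)
    return out.data[0]


def sigmoid(fm: np.ndarray) -> np.ndarray:
    """Elementwise logistic function, range (0, 1)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(fm, dtype=np.float64)))


def channel_attention(fm: np.ndarray, beta_attn: float) -> np.ndarray:
    """Channel attention: softmax over the Gram matrix of channel vectors.

    ``AS`` is the row-softmax of the C x C Gram matrix of the
    channel-flattened map; the output is
    ``beta * (AS-weighted sum of channels) + fm`` so ``beta = 0`` is
    the identity.
    """
    x = _fm(fm)
    c, h, w = x.shape
    a = x.reshape(c, h * w)
    gram = a @ a.T
    gram -= gram.max(axis=-1, keepdims=True)
    e = np.exp(gram)
    attn = e / e.sum(axis=-1, keepdims=True)
    out = attn @ a
    return (beta_attn * out + a).reshape(c, h, w)


def position_attention(fm: np.ndarray, beta_attn: float) -> np.ndarray:
    """Position attention with identity query/key/value projections.

    The energy matrix is the (HW) x (HW) Gram matrix of pixel feature
    vectors; its row-softmax gives the position attention weights used
    to aggregate values, scaled by ``beta`` and added residually.
    """
    x = _fm(fm)
    c, h, w = x.shape
    a = x.reshape(c, h * w)
    energy = a.T @ a
    energy -= energy.max(axis=-1, keepdims=True)
    e = np.exp(energy)
    pw = e / e.sum(axis=-1, keepdims=True)
    out = a @ pw.T  # position j aggregates values with its attention row
    return (beta_attn * out + a).reshape(c, h, w)


# ---------------------------------------------------------------------
# network modules
# ---------------------------------------------------------------------


class ChannelAttentionBlock(nn.Module):
    """Learnable-scale channel attention (beta initialized to 0)."""

    def __init__(self):
        super().__init__()
        self.beta = Tensor(np.zeros(1), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        a = E.reshape(x, (n, c, h * w))
        gram = E.matmul(a, E.transpose(a, (0, 2, 1)))
        attn = E.softmax(gram, axis=-1)
        out = E.matmul(attn, a)
        return E.reshape(E.add(E.mul(self.beta, out), a), (n, c, h, w))


class PositionAttentionBlock(nn.Module):
    """Learnable-scale position attention with 1x1 query/key/value convs."""

    def __init__(self, c: int, rng: np.random.Generator, projections: bool = True):
        super().__init__()
        self.beta = Tensor(np.zeros(1), requires_grad=True)
        self.projections = projections
        if projections:
            self.query = nn.Conv2d(c, c, 1, rng)
            self.key = nn.Conv2d(c, c, 1, rng)
            self.value = nn.Conv2d(c, c, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        q = self.query(x) if self.projections else x
        k = self.key(x) if self.projections else x
        v = self.value(x) if self.projections else x
        qf = E.reshape(q, (n, c, h * w))
        kf = E.reshape(k, (n, c, h * w))
        vf = E.reshape(v, (n, c, h * w))
        energy = E.matmul(E.transpose(qf, (0, 2, 1)), kf)
        pw = E.softmax(energy, axis=-1)
        out = E.matmul(vf, E.transpose(pw, (0, 2, 1)))
        res = E.reshape(x, (n, c, h * w))
        return E.reshape(E.add(E.mul(self.beta, out), res), (n, c, h, w))


class PositionBlock1(nn.Module):
    """Original-scale position branch: depthwise 3x3 -> BN -> 1x1 conv."""

    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        self.dw = nn.DepthwiseConv2d(c, 3, rng)
        self.bn = nn.BatchNorm2d(c)
        self.pw = nn.Conv2d(c, c, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.pw(self.bn(self.dw(x)))


class ContextBlock1(nn.Module):
    """Small-scale context branch: depthwise 3x3 -> BN -> 1x1 conv -> sigmoid."""

    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        self.dw = nn.DepthwiseConv2d(c, 3, rng)
        self.bn = nn.BatchNorm2d(c)
        self.pw = nn.Conv2d(c, c, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return E.sigmoid(self.pw(self.bn(self.dw(x))))


class ContextBlock2(nn.Module):
    """Original-scale context branch.

    Two stride-2 3x3 convolutions take the map to quarter scale, then
    BN, a 1x1 conv, a x4 bilinear upsample back to the original grid
    and a sigmoid, yielding a (0, 1) context weight map.
    """

    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        self.down1 = nn.Conv2d(c, c, 3, rng, stride=2, pad=1)
        self.down2 = nn.Conv2d(c, c, 3, rng, stride=2, pad=1)
        self.bn = nn.BatchNorm2d(c)
        self.pw = nn.Conv2d(c, c, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.pw(self.bn(self.down2(self.down1(x))))
        return E.sigmoid(E.upsample_bilinear(y, 4))


class PositionBlock2(nn.Module):
    """Small-scale position branch.

    The strided chain (3x3 stride-2 conv -> BN -> 1x1 conv -> 3x3
    stride-2 average pool) runs on a x4 bilinearly pre-upsampled copy
    of the quarter-scale map, so both stride-2 stages are present while
    the output lands back on the quarter-scale grid.
    """

    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        self.down = nn.Conv2d(c, c, 3, rng, stride=2, pad=1)
        self.bn = nn.BatchNorm2d(c)
        self.pw = nn.Conv2d(c, c, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        y = E.upsample_bilinear(x, 4)
        y = self.pw(self.bn(self.down(y)))
        return E.avg_pool2d(y, 3, stride=2, pad=1)


class FFCFuse(nn.Module):
    """Two-scale position/context fusion producing the optimized map."""

    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        self.position1 = PositionBlock1(c, rng)
        self.context1 = ContextBlock1(c, rng)
        self.context2 = ContextBlock2(c, rng)
        self.position2 = PositionBlock2(c, rng)

    def forward(self, fm_orig: Tensor, fm_small: Tensor) -> Tensor:
        ho, wo = fm_orig.data.shape[2:]
        hs, ws = fm_small.data.shape[2:]
        if (hs * 4, ws * 4) != (ho, wo):
            raise ValueError(
                f"small map {hs}x{ws} must be a quarter of the original {ho}x{wo}"
            )
        os_out = E.mul(self.position1(fm_orig), self.context2(fm_orig))
        ss_out = E.mul(self.context1(fm_small), self.position2(fm_small))
        return E.add(os_out, E.mul(E.upsample_bilinear(ss_out, 4), 4.0))


class FFCModule(nn.Module):
    """Dual attention plus two-scale fusion at the bottleneck.

    The quarter-scale companion map is produced from the (attention
    refined) original map by two stride-2 3x3 convolutions.
    """

    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        self.channel_attn = ChannelAttentionBlock()
        self.position_attn = PositionAttentionBlock(c, rng)
        self.small1 = nn.Conv2d(c, c, 3, rng, stride=2, pad=1)
        self.small2 = nn.Conv2d(c, c, 3, rng, stride=2, pad=1)
        self.fuse = FFCFuse(c, rng)

    def forward(self, x: Tensor) -> Tensor:
        # sum of the two attention branches minus the shared residual
        att = E.add(E.add(self.channel_attn(x), self.position_attn(x)), E.mul(x, -1.0))
        small = E.relu(self.small2(E.relu(self.small1(att))))
        return self.fuse(att, small)


class AttentionGate(nn.Module):
    """Additive attention gate filtering a skip connection.

    1x1 convs project the skip ``x`` and the (upsampled) gating signal
    ``g`` to a common intermediate width; their sum passes, in the
    modified variant, through batch norm, ReLU and dropout before the
    final 1x1 conv and sigmoid produce the coefficient map ``alpha``
    broadcast over channels.  The default variant omits BN and dropout.
    """

    def __init__(self, cx: int, cg: int, rng: np.random.Generator,
                 variant: str = "modified", dropout_rate: float = 0.1):
        super().__init__()
        if variant not in ("default", "modified"):
            raise ValueError("gate variant must be 'default' or 'modified'")
        self.variant = variant
        cint = max(cx // 2, 1)
        self.wx = nn.Conv2d(cx, cint, 1, rng)
        self.wg = nn.Conv2d(cg, cint, 1, rng)
        self.bn = nn.BatchNorm2d(cint) if variant == "modified" else None
        self.drop = nn.Dropout(dropout_rate, rng) if variant == "modified" else None
        self.psi = nn.Conv2d(cint, 1, 1, rng)

    def forward(self, x: Tensor, g: Tensor) -> Tensor:
        if g.data.shape[2] != x.data.shape[2]:
            scale = x.data.shape[2] // g.data.shape[2]
            if scale * g.data.shape[2] != x.data.shape[2]:
                raise ValueError("gating signal size incompatible with skip")
            g = E.upsample_bilinear(g, scale)
        s = E.add(self.wx(x), self.wg(g))
        if self.variant == "modified":
            s = self.drop(E.relu(self.bn(s)))
        else:
            s = E.relu(s)
        alpha = E.sigmoid(self.psi(s))
        return E.mul(x, alpha)


def attention_gate(x: np.ndarray, g: np.ndarray, dropout_rate: float = 0.1,
                   seed: int = 0, variant: str = "modified") -> np.ndarray:
    """Functional gate on C x H x W maps with seeded weights (eval mode)."""
    gate = AttentionGate(x.shape[0], g.shape[0], np.random.default_rng(seed),
                         variant=variant, dropout_rate=dropout_rate)
    gate.eval()
    return gate(Tensor(_fm(x)[None]), Tensor(_fm(g)[None])).data[0]


def ffc_fuse(fm_orig: np.ndarray, fm_small: np.ndarray, seed: int = 0) -> np.ndarray:
    """Functional two-scale fusion with seeded weights (eval mode)."""
    fuse = FFCFuse(fm_orig.shape[0], np.random.default_rng(seed))
    fuse.eval()
    return fuse(Tensor(_fm(fm_orig)[None]), Tensor(_fm(fm_small)[None])).data[0]


# ---------------------------------------------------------------------
# the full network
# ---------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Architecture switches; the ablation lattice lives here.

    ``attention_gate``: 'none' (skips pass by plain concatenation),
    'default', or 'modified' (adds BN + dropout inside the gate).
    ``ffcm_enabled`` toggles the bottleneck FFC module.
    """

    input_size: tuple[int, int] = (64, 64)
    base_channels: int = 8
    depth: int = 4
    dropout_rate: float = 0.1
    attention_gate: str = "modified"
    ffcm_enabled: bool = True
    mask_head: bool = False
    seed: int = 0

    def __post_init__(self):
        h, w = self.input_size
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if h % (2 ** self.depth) or w % (2 ** self.depth):
            raise ValueError(
                f"input size {self.input_size} must be divisible by 2^depth"
            )
        if self.attention_gate not in ("none", "default", "modified"):
            raise ValueError("attention_gate must be none|default|modified")


class ConvBlock(nn.Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.c1 = nn.Conv2d(cin, cout, 3, rng)
        self.b1 = nn.BatchNorm2d(cout)
        self.c2 = nn.Conv2d(cout, cout, 3, rng)
        self.b2 = nn.BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return E.relu(self.b2(self.c2(E.relu(self.b1(self.c1(x))))))


class FCAUNet(nn.Module):
    """Encoder/decoder with attention-gated skips and a bottleneck FFC.

    ``forward`` returns class logits (and the mask map when the mask
    head is enabled) and records named intermediate activations in
    ``self.activations`` for Grad-CAM.
    """

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.rng = rng
        chans = [config.base_channels * (2 ** i) for i in range(config.depth)]
        cb = config.base_channels * (2 ** config.depth)

        self.encoders = []
        cin = 1
        for c in chans:
            self.encoders.append(ConvBlock(cin, c, rng))
            cin = c
        self.bottleneck = ConvBlock(chans[-1], cb, rng)
        self.ffc = FFCModule(cb, rng) if config.ffcm_enabled else None

        self.upconvs = []
        self.gates = []
        self.decoders = []
        state = cb
        for c in reversed(chans):
            self.upconvs.append(nn.Conv2d(state, c, 3, rng))
            if config.attention_gate != "none":
                self.gates.append(AttentionGate(c, state, rng,
                                                variant=config.attention_gate,
                                                dropout_rate=config.dropout_rate))
            self.decoders.append(ConvBlock(2 * c, c, rng))
            state = c
        self.head = nn.Linear(chans[0], 2, rng)
        self.mask_conv = nn.Conv2d(chans[0], 1, 1, rng) if config.mask_head else None
        self.activations: dict[str, Tensor] = {}

    def forward(self, x: Tensor):
        h, w = self.config.input_size
        if x.data.ndim != 4 or x.data.shape[1:] != (1, h, w):
            raise ValueError(f"expected input (N, 1, {h}, {w}), got {x.data.shape}")
        self.activations = {}
        skips = []
        t = x
        for i, enc in enumerate(self.encoders):
            t = enc(t)
            self.activations[f"encoder{i}"] = t
            skips.append(t)
            t = E.max_pool2d(t, 2)
        t = self.bottleneck(t)
        if self.ffc is not None:
            t = self.ffc(t)
        self.activations["bottleneck"] = t
        for i, (up, dec) in enumerate(zip(self.upconvs, self.decoders)):
            skip = skips[-(i + 1)]
            if self.gates:
                skip = self.gates[i](skip, t)
            t = up(E.upsample_bilinear(t, 2))
            t = dec(E.concat([t, skip], axis=1))
            self.activations[f"decoder{i}"] = t
        logits = self.head(E.global_avg_pool(t))
        if self.mask_conv is not None:
            mask = E.sigmoid(self.mask_conv(t))
            return logits, mask
        return logits, None


def build_fcau_net(config: ModelConfig) -> FCAUNet:
    """Construct a seeded FCAU-Net; identical configs yield identical weights."""
    return FCAUNet(config)


# ---------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------


@dataclass
class TrainParams:
    """Optimization hyperparameters (class-weighted cross-entropy + Adam)."""

    epochs: int = 30
    batch_size: int = 8
    lr: float = 3e-3
    mask_loss_weight: float = 0.5  # Dice weight when masks are supplied
    early_stop_val_acc: Optional[float] = None  # stop once val accuracy reached


def _to_arrays(samples: Sequence[LabeledSample], with_masks: bool):
    x = np.stack([s.image.astype(np.float64) / (s.gray_levels - 1) for s in samples])
    y = np.array([LABELS.index(s.label) for s in samples])
    m = None
    if with_masks and all(s.mask is not None for s in samples):
        m = np.stack([s.mask.astype(np.float64) for s in samples])
    return x[:, None], y, m


def _dice_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Soft Dice loss between a (N,1,H,W) prediction and binary masks."""
    t = target[:, None]
    inter = E.tsum(E.mul(pred, t))
    denom = E.add(E.tsum(pred), float(t.sum()))
    dice = E.mul(inter, 2.0)
    # 1 - 2|PG| / (|P| + |G|); smooth by 1 to keep empty masks finite
    num = E.add(dice, 1.0)
    den = E.add(denom, 1.0)
    frac_data = num.data / den.data

    def backward(g):
        if num.requires_grad:
            num._accum(g / den.data)
        if den.requires_grad:
            den._accum(-g * num.data / den.data**2)

    frac = Tensor(frac_data, requires_grad=True, parents=(num, den), backward=backward)
    return E.add(E.mul(frac, -1.0), 1.0)


def train_model(
    model: FCAUNet,
    train_set: Sequence[LabeledSample],
    val_set: Sequence[LabeledSample],
    params: TrainParams = TrainParams(),
    seed: int = 0,
) -> tuple[FCAUNet, list[dict]]:
    """Train with class-weighted cross-entropy (+ Dice when masks exist).

    Returns the model and a per-epoch history of mean training loss and
    validation accuracy.  Fully deterministic under (model seed, seed).
    """
    if not train_set:
        raise ValueError("training set is empty")
    labels = {s.label for s in train_set}
    if len(labels) < 2:
        raise ValueError("training data must contain both classes")
    use_masks = model.config.mask_head and all(s.mask is not None for s in train_set)
    x, y, masks = _to_arrays(train_set, use_masks)
    counts = np.bincount(y, minlength=2).astype(np.float64)
    class_w = counts.sum() / (2.0 * np.maximum(counts, 1.0))
    xv, yv, _ = _to_arrays(val_set, False) if val_set else (None, None, None)

    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), lr=params.lr)
    history: list[dict] = []
    n = len(train_set)
    for epoch in range(params.epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, params.batch_size):
            idx = order[lo:lo + params.batch_size]
            model.zero_grad()
            logits, mask_pred = model(Tensor(x[idx]))
            loss = E.cross_entropy_logits(logits, y[idx], class_w)
            if use_masks and mask_pred is not None:
                loss = E.add(loss, E.mul(_dice_loss(mask_pred, masks[idx]),
                                         params.mask_loss_weight))
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        entry = {"epoch": epoch, "loss": float(np.mean(losses))}
        if xv is not None:
            pred_labels, _, _ = predict(model, xv)
            entry["val_accuracy"] = float(np.mean(pred_labels == yv))
        history.append(entry)
        if (params.early_stop_val_acc is not None
                and entry.get("val_accuracy", 0.0) >= params.early_stop_val_acc):
            break
    model.eval()
    return model, history


def predict(model: FCAUNet, images, batch_size: int = 16):
    """Class labels, probabilities and optional masks for a batch of images.

    ``images`` may be an (N,1,H,W) float array in [0,1] or a sequence of
    :class:`LabeledSample` / 2-D integer images.
    """
    if isinstance(images, np.ndarray) and images.ndim == 4:
        x = images.astype(np.float64)
    else:
        imgs = [s.image if isinstance(s, LabeledSample) else np.asarray(s)
                for s in images]
        x = np.stack([im.astype(np.float64) / 255.0 for im in imgs])[:, None]
    model.eval()
    probs_all, masks_all = [], []
    for lo in range(0, x.shape[0], batch_size):
        logits, mask = model(Tensor(x[lo:lo + batch_size]))
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        probs_all.append(p)
        if mask is not None:
            masks_all.append(mask.data[:, 0])
    probs = np.concatenate(probs_all)
    masks = np.concatenate(masks_all) if masks_all else None
    return probs.argmax(axis=1), probs, masks


def _ckpt_base(path: str) -> str:
    p = str(path)
    return p[:-4] if p.endswith(".npz") else p


def save_checkpoint(model: FCAUNet, path: str) -> None:
    """Single-file weights (.npz) plus a JSON sidecar with the config."""
    base = _ckpt_base(path)
    np.savez(base + ".npz", **model.state_arrays())
    with open(base + ".json", "w") as fh:
        json.dump({"config": asdict(model.config)}, fh, indent=2)


def load_checkpoint(path: str) -> FCAUNet:
    base = _ckpt_base(path)
    with open(base + ".json") as fh:
        meta = json.load(fh)
    cfg = meta["config"]
    cfg["input_size"] = tuple(cfg["input_size"])
    model = FCAUNet(ModelConfig(**cfg))
    npz = np.load(base + ".npz")
    model.load_state_arrays({k: npz[k] for k in npz.files})
    model.eval()
    return model
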