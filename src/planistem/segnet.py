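"""U-Net segmentation: architecture, loss, training and inference.

The network is a standard U-Net: per encoder level two 3x3 convolutions
(ReLU) followed by 2x2 max-pooling; a two-convolution bottleneck; per
decoder level factor-2 nearest upsampling, a 2x2 convolution halving the
channels, skip concatenation and two 3x3 convolutions; and a head of one
3x3 convolution to 2 channels plus a 1x1 convolution to a single channel
with logistic output.  The canonical configuration (depth 5, base width
64, width factor 2, 128x128 single-channel input) has exactly 31,031,685
trainable parameters.

The loss is the sum of a Dice loss and a class- and contour-weighted
binary cross-entropy: every pixel is weighted by
``log(1 + |I|/|I_k| + 1_C(i) |I|/|C_k|)`` where ``I_k`` is the pixel's
class and ``C_k`` the class contour, so minority-class and boundary
pixels dominate the gradient.  This prevents the trivial background-only
solution on images where the target structure covers only a few percent
of the pixels.

Training runs for a fixed number of epochs with on-the-fly geometric
augmentation (random shifts, rotations and zooms applied identically to
image and mask) and retains the weights with the best validation score.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import _nn
from .phantom import ROI_SHAPE

__all__ = [
    "UNetConfig", "TrainConfig", "UNet", "build_unet",
    "dice_loss", "weight_map", "weighted_ce", "combined_loss",
    "dice_coefficient", "train", "predict", "save_model", "load_model",
    "TASKS", "TINY_CONFIG",
]

#: the four segmentation tasks; one independent model per task
TASKS = ("midbrain_area", "midbrain_ellipse", "pons_area", "pons_ellipse")


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters.

    The defaults are the canonical configuration; a reduced variant (see
    :data:`TINY_CONFIG`) is practical for CPU-scale training runs.
    """

    input_shape: tuple[int, int] = ROI_SHAPE
    in_channels: int = 1
    depth: int = 5
    base_width: int = 64
    width_factor: int = 2

    def level_widths(self) -> list[int]:
        return [self.base_width * self.width_factor ** i
                for i in range(self.depth)]

    def validate(self) -> None:
        h, w = self.input_shape
        f = 2 ** (self.depth - 1)
        if h % f or w % f:
            raise ValueError(
                f"input shape {self.input_shape} is not divisible by "
                f"2^(depth-1) = {f}; spatial sizes would not be integral")


#: scaled-down configuration used for CPU training runs
TINY_CONFIG = UNetConfig(depth=3, base_width=8)


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: 30 epochs, batch 4, shift/rotate/zoom augmentation."""

    epochs: int = 30
    batch_size: int = 4
    shift_px: float = 10.0
    rotation_deg: float = 15.0
    zoom: tuple[float, float] = (0.8, 1.2)
    selection_metric: str = "val_loss"  # or "val_accuracy"
    learning_rate: float = 1e-3
    seed: int = 0


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------

def build_unet(cfg: UNetConfig) -> dict:
    """Layer-by-layer description of the network with parameter counts.

    Purely arithmetic; no weights are allocated.  The canonical
    configuration totals 31,031,685 trainable parameters.
    """
    cfg.validate()
    widths = cfg.level_widths()
    h, w = cfg.input_shape
    layers = []

    def conv(name, cin, cout, k, hh, ww):
        layers.append({"name": name, "kernel": (k, k), "in": cin,
                       "out": cout, "shape": (hh, ww),
                       "params": (cin * k * k + 1) * cout})

    cin = cfg.in_channels
    hh, ww = h, w
    for lvl in range(cfg.depth - 1):
        conv(f"enc{lvl}_conv1", cin, widths[lvl], 3, hh, ww)
        conv(f"enc{lvl}_conv2", widths[lvl], widths[lvl], 3, hh, ww)
        cin = widths[lvl]
        hh, ww = hh // 2, ww // 2
        layers.append({"name": f"enc{lvl}_pool", "kernel": (2, 2),
                       "in": cin, "out": cin, "shape": (hh, ww), "params": 0})
    conv("bottleneck_conv1", cin, widths[-1], 3, hh, ww)
    conv("bottleneck_conv2", widths[-1], widths[-1], 3, hh, ww)
    cin = widths[-1]
    for lvl in range(cfg.depth - 2, -1, -1):
        hh, ww = hh * 2, ww * 2
        layers.append({"name": f"dec{lvl}_upsample", "kernel": (2, 2),
                       "in": cin, "out": cin, "shape": (hh, ww), "params": 0})
        conv(f"dec{lvl}_upconv", cin, widths[lvl], 2, hh, ww)
        conv(f"dec{lvl}_conv1", widths[lvl] * 2, widths[lvl], 3, hh, ww)
        conv(f"dec{lvl}_conv2", widths[lvl], widths[lvl], 3, hh, ww)
        cin = widths[lvl]
    conv("head_conv3x3", cin, 2, 3, hh, ww)
    conv("head_conv1x1", 2, 1, 1, hh, ww)
    total = int(sum(l["params"] for l in layers))
    return {"layers": layers, "total_params": total,
            "output_shape": (hh, ww)}


_PAD3 = ((1, 1), (1, 1))
_PAD2 = ((0, 1), (0, 1))
_PAD1 = ((0, 0), (0, 0))


class UNet:
    """A U-Net instance with NumPy weights and manual backprop."""

    def __init__(self, cfg: UNetConfig, seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        self.description = build_unet(cfg)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        for layer in self.description["layers"]:
            if layer["params"] == 0:
                continue
            k = layer["kernel"][0]
            self.params[layer["name"] + ".w"] = _nn.he_init(
                rng, layer["out"], layer["in"], k, k)
            self.params[layer["name"] + ".b"] = np.zeros(layer["out"],
                                                         dtype=np.float32)

    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward / backward -------------------------------------------------
    def _conv_relu(self, name, x, pad, cache, relu=True):
        w = self.params[name + ".w"]
        b = self.params[name + ".b"]
        y = _nn.conv2d_forward(x, w, b, pad)
        if relu:
            y = _nn.relu_forward(y)
        cache[name] = (x, y, pad, relu)
        return y

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Logits of shape (B, 1, H, W); optionally the backprop cache."""
        cfg = self.cfg
        cache: dict = {}
        skips = []
        dtype = next(iter(self.params.values())).dtype
        h = np.ascontiguousarray(x, dtype=dtype)
        for lvl in range(cfg.depth - 1):
            h = self._conv_relu(f"enc{lvl}_conv1", h, _PAD3, cache)
            h = self._conv_relu(f"enc{lvl}_conv2", h, _PAD3, cache)
            skips.append(h)
            h, idx = _nn.maxpool2_forward(h)
            cache[f"enc{lvl}_pool"] = (idx, skips[-1].shape)
        h = self._conv_relu("bottleneck_conv1", h, _PAD3, cache)
        h = self._conv_relu("bottleneck_conv2", h, _PAD3, cache)
        for lvl in range(cfg.depth - 2, -1, -1):
            h = _nn.upsample2_forward(h)
            h = self._conv_relu(f"dec{lvl}_upconv", h, _PAD2, cache)
            skip = skips[lvl]
            h = np.concatenate([skip, h], axis=1)
            cache[f"dec{lvl}_concat"] = skip.shape[1]
            h = self._conv_relu(f"dec{lvl}_conv1", h, _PAD3, cache)
            h = self._conv_relu(f"dec{lvl}_conv2", h, _PAD3, cache)
        # the two head convolutions are linear: a ReLU on a 2-channel
        # bottleneck can die irrecoverably, freezing the whole network
        h = self._conv_relu("head_conv3x3", h, _PAD3, cache, relu=False)
        logits = self._conv_relu("head_conv1x1", h, _PAD1, cache, relu=False)
        return (logits, cache) if want_cache else logits

    def _conv_back(self, name, dy, cache, grads):
        x, y, pad, relu = cache[name]
        if relu:
            dy = _nn.relu_backward(dy, y)
        dx, dw, db = _nn.conv2d_backward(dy, x, self.params[name + ".w"], pad)
        grads[name + ".w"] = dw
        grads[name + ".b"] = db
        return dx

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict:
        """Full backward pass (head -> decoder -> bottleneck -> encoder)."""
        cfg = self.cfg
        grads: dict[str, np.ndarray] = {}
        dy = self._conv_back("head_conv1x1", dlogits, cache, grads)
        dy = self._conv_back("head_conv3x3", dy, cache, grads)
        dskips: dict[int, np.ndarray] = {}
        # the decoder was run for lvl = depth-2 .. 0, so reverse it 0-first
        for lvl in range(cfg.depth - 1):
            dy = self._conv_back(f"dec{lvl}_conv2", dy, cache, grads)
            dy = self._conv_back(f"dec{lvl}_conv1", dy, cache, grads)
            n_skip = cache[f"dec{lvl}_concat"]
            dskips[lvl] = dy[:, :n_skip]
            dy = self._conv_back(f"dec{lvl}_upconv", dy[:, n_skip:], cache,
                                 grads)
            dy = _nn.upsample2_backward(dy)
        dy = self._conv_back("bottleneck_conv2", dy, cache, grads)
        dy = self._conv_back("bottleneck_conv1", dy, cache, grads)
        for lvl in range(cfg.depth - 2, -1, -1):
            idx, shape = cache[f"enc{lvl}_pool"]
            dy = _nn.maxpool2_backward(dy, idx, shape)
            dy = dy + dskips[lvl]
            dy = self._conv_back(f"enc{lvl}_conv2", dy, cache, grads)
            dy = self._conv_back(f"enc{lvl}_conv1", dy, cache, grads)
        return grads


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

_CROSS = ndimage.generate_binary_structure(2, 1)


def dice_loss(g: np.ndarray, p: np.ndarray, eps: float = 1.0) -> float:
    """``1 - 2 sum(GP) / (sum(G) + sum(P))`` with smoothing ``eps``."""
    g = np.asarray(g, dtype=float)
    p = np.asarray(p, dtype=float)
    if g.shape != p.shape:
        raise ValueError("shape mismatch between mask and probabilities")
    num = 2.0 * float((g * p).sum()) + eps
    den = float(g.sum() + p.sum()) + eps
    return 1.0 - num / den


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Plain Dice overlap of two binary masks (1 when both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    sa, sb = int(a.sum()), int(b.sum())
    if sa == 0 and sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def weight_map(g: np.ndarray, connectivity: int = 4) -> np.ndarray:
    """Class- and contour-aware pixel weights.

    ``w[i] = log(1 + |I|/|I_k(i)| + 1_C(i) |I|/|C_k(i)|)`` where ``k(i)``
    is the pixel's class, ``C_1`` the structure pixels adjacent to the
    background and ``C_0`` the background pixels adjacent to the
    structure (4-adjacency by default).  Requires both classes present.
    """
    g = np.asarray(g).astype(bool)
    n_fg = int(g.sum())
    n_total = g.size
    if n_fg == 0 or n_fg == n_total:
        raise ValueError("weight map is undefined for a single-class mask")
    if connectivity == 4:
        st = _CROSS
    elif connectivity == 8:
        st = np.ones((3, 3), dtype=bool)
    else:
        raise ValueError("connectivity must be 4 or 8")
    c1 = g & ~ndimage.binary_erosion(g, structure=st, border_value=0)
    c0 = ~g & ndimage.binary_dilation(g, structure=st, border_value=0)
    w = np.empty(g.shape, dtype=float)
    w[g] = n_total / n_fg
    w[~g] = n_total / (n_total - n_fg)
    if c1.any():
        w[c1] += n_total / int(c1.sum())
    if c0.any():
        w[c0] += n_total / int(c0.sum())
    return np.log1p(w)


def weighted_ce(g: np.ndarray, p: np.ndarray, w: np.ndarray,
                eps: float = 1e-7) -> float:
    """Weighted binary cross-entropy, summed over pixels."""
    g = np.asarray(g, dtype=float)
    p = np.asarray(p, dtype=float)
    if g.shape != p.shape or g.shape != np.shape(w):
        raise ValueError("shape mismatch")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-(w * (g * np.log(p) + (1.0 - g) * np.log1p(-p))).sum())


def combined_loss(g: np.ndarray, p: np.ndarray) -> float:
    """Sum of Dice loss and contour-weighted cross-entropy."""
    return dice_loss(g, p) + weighted_ce(g, p, weight_map(g))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def augment_pair(image: np.ndarray, mask: np.ndarray,
                 rng: np.random.Generator, cfg: TrainConfig):
    """Random shift/rotation/zoom applied identically to image and mask.

    Linear interpolation for the image, nearest-neighbor for the mask.
    """
    h, w = image.shape
    shift = rng.uniform(-cfg.shift_px, cfg.shift_px, size=2)
    angle = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
    zoom = rng.uniform(*cfg.zoom)
    c, s = np.cos(angle), np.sin(angle)
    # output -> input mapping about the image center, then shift
    m = np.array([[c, -s], [s, c]]) / zoom
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - m @ (center + shift)
    img_t = ndimage.affine_transform(image, m, offset=offset, order=1,
                                     mode="constant", cval=float(
                                         np.median(image)))
    mask_t = ndimage.affine_transform(mask.astype(np.float32), m,
                                      offset=offset, order=0,
                                      mode="constant", cval=0.0)
    return img_t.astype(np.float32), mask_t > 0.5


def _loss_and_grad(g: np.ndarray, p: np.ndarray, w: np.ndarray,
                   eps_dice: float = 1.0, eps_p: float = 1e-7):
    """Combined loss value and its gradient w.r.t. the logits, per sample."""
    num = 2.0 * (g * p).sum() + eps_dice
    den = g.sum() + p.sum() + eps_dice
    l_dice = 1.0 - num / den
    pc = np.clip(p, eps_p, 1.0 - eps_p)
    l_wce = -(w * (g * np.log(pc) + (1.0 - g) * np.log1p(-pc))).sum()
    d_dice_dp = -(2.0 * g * den - num) / den ** 2
    dlogits = d_dice_dp * p * (1.0 - p) + w * (p - g)
    return float(l_dice + l_wce), dlogits.astype(np.float32)


def _evaluate(net: UNet, pairs, threshold=0.5):
    losses, dices, accs = [], [], []
    for img, msk in pairs:
        p = _nn.sigmoid(net.forward(img[None, None].astype(np.float32))
                        )[0, 0].astype(float)
        losses.append(combined_loss(msk, p))
        dices.append(dice_coefficient(msk, p >= threshold))
        accs.append(float(((p >= threshold) == msk.astype(bool)).mean()))
    return (float(np.mean(losses)), float(np.mean(dices)),
            float(np.mean(accs)))


def train(net: UNet, train_pairs, val_pairs, cfg: TrainConfig
          ) -> tuple[dict, list[dict]]:
    """Train with augmentation; return best-validation weights + history.

    ``train_pairs`` / ``val_pairs`` are sequences of (image, mask) with
    images in [0, 1] and boolean masks.  Model selection uses
    ``cfg.selection_metric``: validation combined loss (minimized, the
    default) or validation pixel accuracy (maximized).
    """
    if not train_pairs or not val_pairs:
        raise ValueError("training and validation sets must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    opt = _nn.Adam(net.params, lr=cfg.learning_rate)
    history: list[dict] = []
    best_state = {k: v.copy() for k, v in net.params.items()}
    best_score = -np.inf
    n = len(train_pairs)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            batch = [train_pairs[i] for i in order[start:start
                                                   + cfg.batch_size]]
            imgs, msks, wmaps = [], [], []
            for img, msk in batch:
                ai, am = augment_pair(img, msk, rng, cfg)
                if not am.any() or am.all():
                    ai, am = img.astype(np.float32), msk.astype(bool)
                imgs.append(ai)
                msks.append(am)
                wmaps.append(weight_map(am))
            x = np.stack(imgs)[:, None]
            logits, cache = net.forward(x, want_cache=True)
            p = _nn.sigmoid(logits)[:, 0].astype(float)
            dlog = np.empty_like(logits)
            for i in range(len(batch)):
                li, di = _loss_and_grad(msks[i].astype(float), p[i],
                                        wmaps[i])
                epoch_loss += li
                dlog[i, 0] = di
            grads = net.backward(dlog / len(batch), cache)
            opt.step(net.params, grads)
        val_loss, val_dice, val_acc = _evaluate(net, val_pairs)
        history.append({"epoch": epoch, "train_loss": epoch_loss / n,
                        "val_loss": val_loss, "val_dice": val_dice,
                        "val_accuracy": val_acc})
        score = -val_loss if cfg.selection_metric == "val_loss" else val_acc
        if score > best_score:
            best_score = score
            best_state = {k: v.copy() for k, v in net.params.items()}
    net.params = {k: v.copy() for k, v in best_state.items()}
    return best_state, history


def predict(net: UNet, image: np.ndarray, threshold: float = 0.5
            ) -> tuple[np.ndarray, np.ndarray]:
    """Probability mask and thresholded binary mask for one image."""
    image = np.asarray(image, dtype=np.float32)
    if image.shape != tuple(net.cfg.input_shape):
        raise ValueError(
            f"image shape {image.shape} does not match model input "
            f"{net.cfg.input_shape}")
    prob = _nn.sigmoid(net.forward(image[None, None]))[0, 0].astype(float)
    return prob, prob >= threshold


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(net: UNet, path: str | Path, history: list[dict] | None = None,
               meta: dict | None = None) -> None:
    """Weights to ``<path>`` (npz) with a JSON sidecar ``<path>.json``."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    np.savez(path, **net.params)
    sidecar = {"config": asdict(net.cfg), "history": history or [],
               "meta": meta or {}}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> UNet:
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    cfg_d = sidecar["config"]
    cfg = UNetConfig(input_shape=tuple(cfg_d["input_shape"]),
                     in_channels=cfg_d["in_channels"],
                     depth=cfg_d["depth"], base_width=cfg_d["base_width"],
                     width_factor=cfg_d["width_factor"])
    net = UNet(cfg)
    with np.load(path) as data:
        net.params = {k: data[k].astype(np.float32) for k in data.files}
    return net
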