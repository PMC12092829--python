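"""The scanning attention U-Net: architecture, loss, training, inference.

"Scanning" means the network is a 2D encoder-decoder applied
section-by-section through a 3D volume; the input contract is the 4-tensor
``[batch, channel=1, H, W]`` of single grayscale sections.  The encoder is
five channel levels of paired same-padding 3x3 convolutions (base, 2*base,
..., 16*base) with batch normalization and ReLU, 2x max pooling between
levels.  The decoder mirrors it with 2x2 transposed-convolution upsampling
(nearest+1x1-conv available as a config option), additive attention gates
on every skip connection, and a final 1x1 convolution to six classes with
channel softmax (no batch norm on the final layer).

Training minimizes a multiclass Tversky loss — a generalized Dice loss
with asymmetric false-positive/false-negative weights alpha and beta —
with AdamW and a learning rate decaying by a fixed factor per epoch.
Everything is plain float32 NumPy and deterministic given the seeds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from sbfseg import nn
from sbfseg.preprocess import SliceBatch
from sbfseg.volumes import N_CLASSES

F32 = np.float32


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    Defaults are the full-scale architecture (base 64 channels, 256-pixel
    sections, five channel levels).  Desk-scale runs use
    ``base_channels <= 16`` and ``input_side <= 64``.
    """

    n_classes: int = N_CLASSES
    input_side: int = 256
    base_channels: int = 64
    depth: int = 5
    attention: bool = True
    batch_norm: bool = True
    upsample_mode: str = "transposed"  # or "nearest+conv"

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.input_side % 2 ** (self.depth - 1) != 0:
            raise ValueError(
                f"input_side {self.input_side} not divisible by "
                f"2^(depth-1) = {2 ** (self.depth - 1)}"
            )
        if self.upsample_mode not in ("transposed", "nearest+conv"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule (full-scale defaults)."""

    base_lr: float = 1e-5
    lr_decay_per_epoch: float = 0.95
    epochs: int = 5
    batch_size: int = 8
    tversky_alpha: float = 0.3
    tversky_beta: float = 0.7
    tversky_smooth: float = 1.0
    weight_decay: float = 0.01
    sections_per_epoch: int | None = None  # None = every section each epoch
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.tversky_alpha <= 1 or not 0 < self.tversky_beta <= 1:
            raise ValueError("tversky alpha and beta must lie in (0, 1]")
        if not 0 < self.lr_decay_per_epoch < 1:
            raise ValueError("lr_decay_per_epoch must lie in (0, 1)")

    def epoch_lrs(self) -> list[float]:
        return [self.base_lr * self.lr_decay_per_epoch**e for e in range(self.epochs)]


# ---------------------------------------------------------------------------
# network

class _EncoderStage:
    def __init__(self, cin, cout, cfg, rng, name):
        self.conv1 = nn.Conv2d(cin, cout, 3, rng, name=f"{name}.conv1")
        self.bn1 = nn.BatchNorm2d(cout, name=f"{name}.bn1") if cfg.batch_norm else None
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(cout, cout, 3, rng, name=f"{name}.conv2")
        self.bn2 = nn.BatchNorm2d(cout, name=f"{name}.bn2") if cfg.batch_norm else None
        self.relu2 = nn.ReLU()

    def layers(self):
        out = [self.conv1]
        if self.bn1: out.append(self.bn1)
        out += [self.conv2]
        if self.bn2: out.append(self.bn2)
        return out

    def forward(self, x, train):
        x = self.conv1.forward(x, train)
        if self.bn1: x = self.bn1.forward(x, train)
        x = self.relu1.forward(x, train)
        x = self.conv2.forward(x, train)
        if self.bn2: x = self.bn2.forward(x, train)
        return self.relu2.forward(x, train)

    def backward(self, dy):
        dy = self.relu2.backward(dy)
        if self.bn2: dy = self.bn2.backward(dy)
        dy = self.conv2.backward(dy)
        dy = self.relu1.backward(dy)
        if self.bn1: dy = self.bn1.backward(dy)
        return self.conv1.backward(dy)


class _DecoderStage:
    def __init__(self, c, cfg, rng, name):
        # upsample 2c -> c, gate the skip, convolve the 2c concatenation
        if cfg.upsample_mode == "transposed":
            self.up = nn.ConvTranspose2(2 * c, c, rng, name=f"{name}.up")
            self.up_conv = None
        else:
            self.up = nn.NearestUp2()
            self.up_conv = nn.Conv2d(2 * c, c, 1, rng, bias=True, name=f"{name}.upconv")
        self.att = (nn.AttentionGate(c, c, max(c // 2, 1), rng, name=f"{name}.att")
                    if cfg.attention else None)
        self.conv1 = nn.Conv2d(2 * c, c, 3, rng, name=f"{name}.conv1")
        self.bn1 = nn.BatchNorm2d(c, name=f"{name}.bn1") if cfg.batch_norm else None
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(c, c, 3, rng, name=f"{name}.conv2")
        self.bn2 = nn.BatchNorm2d(c, name=f"{name}.bn2") if cfg.batch_norm else None
        self.relu2 = nn.ReLU()
        self.c = c

    def layers(self):
        out = [self.up] if isinstance(self.up, nn.ConvTranspose2) else []
        if self.up_conv: out.append(self.up_conv)
        if self.att: out.append(self.att)
        out.append(self.conv1)
        if self.bn1: out.append(self.bn1)
        out.append(self.conv2)
        if self.bn2: out.append(self.bn2)
        return out

    def forward(self, x, skip, train):
        g = self.up.forward(x, train)
        if self.up_conv is not None:
            g = self.up_conv.forward(g, train)
        s = self.att.forward(skip, g, train) if self.att else skip
        h = np.concatenate([g, s], axis=1)
        h = self.conv1.forward(h, train)
        if self.bn1: h = self.bn1.forward(h, train)
        h = self.relu1.forward(h, train)
        h = self.conv2.forward(h, train)
        if self.bn2: h = self.bn2.forward(h, train)
        return self.relu2.forward(h, train)

    def backward(self, dy):
        dy = self.relu2.backward(dy)
        if self.bn2: dy = self.bn2.backward(dy)
        dy = self.conv2.backward(dy)
        dy = self.relu1.backward(dy)
        if self.bn1: dy = self.bn1.backward(dy)
        dcat = self.conv1.backward(dy)
        dg, ds = dcat[:, : self.c], dcat[:, self.c:]
        if self.att:
            dskip, dg2 = self.att.backward(np.ascontiguousarray(ds))
            dg = dg + dg2
        else:
            dskip = np.ascontiguousarray(ds)
        dg = np.ascontiguousarray(dg)
        if self.up_conv is not None:
            dg = self.up_conv.backward(dg)
        dx = self.up.backward(dg)
        return dx, dskip


class ScanningUNet:
    """2D attention U-Net applied slice-wise through 3D volumes."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.seed = seed
        B, D = config.base_channels, config.depth
        chans = [B * 2**d for d in range(D)]
        self.enc = []
        cin = 1
        for d, c in enumerate(chans):
            self.enc.append(_EncoderStage(cin, c, config, rng, f"enc{d}"))
            cin = c
        self.pools = [nn.MaxPool2() for _ in range(D - 1)]
        self.dec = [_DecoderStage(chans[d], config, rng, f"dec{d}")
                    for d in range(D - 2, -1, -1)]
        self.final = nn.Conv2d(B, config.n_classes, 1, rng, bias=True, name="final")

    # -- parameters ---------------------------------------------------------
    def _modules(self):
        for st in self.enc:
            yield from st.layers()
        for st in self.dec:
            yield from st.layers()
        yield self.final

    def params(self) -> list[nn.Param]:
        out = []
        for m in self._modules():
            out.extend(m.params())
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.v.size for p in self.params()))

    def state_arrays(self) -> list[np.ndarray]:
        out = []
        for m in self._modules():
            out.extend(m.state_arrays())
        return out

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Probabilities (n, n_classes, H, W) for sections x (n, 1, H, W)."""
        x = np.ascontiguousarray(x, dtype=F32)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected input (n, 1, H, W), got {x.shape}")
        side = self.config.input_side
        if x.shape[2] != side or x.shape[3] != side:
            raise ValueError(f"section size {x.shape[2:]} does not match "
                             f"network input side {side}")
        skips = []
        h = x
        for d, st in enumerate(self.enc):
            h = st.forward(h, train)
            if d < len(self.enc) - 1:
                skips.append(h)
                h = self.pools[d].forward(h, train)
        for st in self.dec:
            h = st.forward(h, skips.pop(), train)
        logits = self.final.forward(h, train)
        p = nn.softmax_channels(logits)
        if train:
            self._p = p
        return p

    def backward(self, dp: np.ndarray) -> None:
        """Accumulate parameter gradients from dL/d(probabilities)."""
        dz = nn.softmax_backward(self._p, dp.astype(F32))
        dh = self.final.backward(dz)
        # backward through decoder stages in reverse (shallow -> deep);
        # dec[-1] consumed the encoder-level-0 skip, so dskips[d] <-> enc d
        dskips = []
        for st in reversed(self.dec):
            dh, dskip = st.backward(dh)
            dskips.append(dskip)
        dx = self.enc[-1].backward(dh)
        for d in range(len(self.enc) - 2, -1, -1):
            dh = self.pools[d].backward(dx) + dskips[d]
            dx = self.enc[d].backward(dh)
        self._p = None

    # -- bookkeeping ---------------------------------------------------------
    def layer_summary(self) -> list[dict]:
        """One row per convolution, mirroring the architecture table layout."""
        cfg = self.config
        rows = []
        size = cfg.input_side
        cin = 1
        for d in range(cfg.depth):
            c = cfg.base_channels * 2**d
            if d > 0:
                size //= 2
            for i, ci in enumerate((cin, c)):
                rows.append(dict(
                    path="encoder", layer=f"conv{2 * d + i + 1}",
                    kernel=(3, 3), out_channels=c, in_channels=ci,
                    out_size=(size, size), attention=False,
                    batch_norm=cfg.batch_norm, activation="ReLU",
                ))
            cin = c
        for j, d in enumerate(range(cfg.depth - 2, -1, -1)):
            c = cfg.base_channels * 2**d
            size *= 2
            for i, ci in enumerate((2 * c, c)):
                rows.append(dict(
                    path="decoder", layer=f"deconv{2 * j + i + 1}",
                    kernel=(3, 3), out_channels=c, in_channels=ci,
                    out_size=(size, size), attention=cfg.attention,
                    batch_norm=cfg.batch_norm, activation="ReLU",
                ))
        rows.append(dict(
            path="decoder", layer="conv",
            kernel=(1, 1), out_channels=cfg.n_classes,
            in_channels=cfg.base_channels, out_size=(size, size),
            attention=cfg.attention, batch_norm=False, activation="SoftMax",
        ))
        return rows


def build_network(config: NetworkConfig, seed: int = 0) -> ScanningUNet:
    """Construct a randomly initialized scanning attention U-Net."""
    return ScanningUNet(config, seed=seed)


# ---------------------------------------------------------------------------
# Tversky loss

def one_hot(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """One-hot encode integer labels (..., H, W) -> (..., C, H, W)."""
    eye = np.eye(n_classes, dtype=F32)
    return np.moveaxis(eye[labels], -1, -3)


def _tversky_terms(pred, truth, alpha, beta):
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if not 0 < alpha <= 1 or not 0 < beta <= 1:
        raise ValueError("alpha and beta must lie in (0, 1]")
    ch_axis = pred.ndim - 3
    axes = tuple(i for i in range(pred.ndim) if i != ch_axis)
    tp = (pred * truth).sum(axis=axes)
    fp = (pred * (1.0 - truth)).sum(axis=axes)
    fn = ((1.0 - pred) * truth).sum(axis=axes)
    denom = tp + alpha * fp + beta * fn
    return tp, denom, axes, ch_axis


def tversky_loss(pred: np.ndarray, truth: np.ndarray,
                 alpha: float = 0.3, beta: float = 0.7,
                 smooth: float = 1.0) -> float:
    """Mean over classes of (1 - Tversky index) on soft predictions.

    ``TI_c = (TP_c + s) / (TP_c + alpha * FP_c + beta * FN_c + s)`` computed
    over all pixels (and batch items, if present), with the usual smoothing
    term ``s`` that keeps classes absent from a section well-behaved: a
    class with no truth mass and vanishing predicted mass scores a perfect
    index instead of pinning the loss.  The loss is zero iff the prediction
    equals the truth exactly, for any ``s``.  With ``smooth=0`` an empty
    denominator is scored as a perfect index.
    """
    tp, denom, _, _ = _tversky_terms(np.asarray(pred, dtype=np.float64),
                                     np.asarray(truth, dtype=np.float64),
                                     alpha, beta)
    if smooth > 0:
        ti = (tp + smooth) / (denom + smooth)
    else:
        ti = np.where(denom > 0, tp / np.where(denom > 0, denom, 1.0), 1.0)
    return float(np.mean(1.0 - ti))


def tversky_loss_grad(pred: np.ndarray, truth: np.ndarray,
                      alpha: float = 0.3, beta: float = 0.7,
                      smooth: float = 1.0) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the soft predictions."""
    pred = np.asarray(pred, dtype=F32)
    truth = np.asarray(truth, dtype=F32)
    tp, denom, axes, ch_axis = _tversky_terms(pred, truth, alpha, beta)
    num = tp + smooth
    den = denom + smooth
    ok = den > 0
    den = np.where(ok, den, 1.0)
    ti = np.where(ok, num / den, 1.0)
    loss = float(np.mean(1.0 - ti))
    C = pred.shape[ch_axis]
    shape = [1] * pred.ndim
    shape[ch_axis] = C
    num_b = num.reshape(shape).astype(F32)
    den_b = den.reshape(shape).astype(F32)
    ok_b = ok.reshape(shape)
    # d(num)/dp = t ; d(den)/dp = t + alpha*(1-t) - beta*t
    dden = truth + alpha * (1.0 - truth) - beta * truth
    dti = (truth * den_b - num_b * dden) / (den_b * den_b)
    dp = np.where(ok_b, -dti / C, 0.0).astype(F32)
    return loss, dp


# ---------------------------------------------------------------------------
# training and inference

def stack_pairs(pairs: list[tuple[SliceBatch, SliceBatch]]
                ) -> tuple[np.ndarray, np.ndarray]:
    """Flatten slice-batch pairs to (X, Y): (N,1,S,S) float32, (N,S,S) int."""
    xs, ys = [], []
    for raw_b, lab_b in pairs:
        if raw_b.slices.shape != lab_b.slices.shape:
            raise ValueError("intensity/label slice shapes differ: "
                             f"{raw_b.slices.shape} vs {lab_b.slices.shape}")
        x = raw_b.slices.astype(F32)
        if np.issubdtype(raw_b.slices.dtype, np.integer):
            x /= F32(255.0)
        xs.append(x)
        ys.append(lab_b.slices.astype(np.uint8))
    if not xs:
        return (np.zeros((0, 1, 0, 0), dtype=F32), np.zeros((0, 0, 0), np.uint8))
    X = np.concatenate(xs, axis=0)[:, None]
    Y = np.concatenate(ys, axis=0)
    return X, Y


def train(
    network: ScanningUNet,
    training: list[tuple[SliceBatch, SliceBatch]] | tuple[np.ndarray, np.ndarray],
    validation: list[tuple[SliceBatch, SliceBatch]] | tuple[np.ndarray, np.ndarray] | None,
    config: TrainConfig,
) -> tuple[ScanningUNet, dict]:
    """AdamW training with the per-epoch decaying learning-rate schedule.

    Sections from all augmentation axes are mixed uniformly in one stream
    and reshuffled every epoch.  ``config.sections_per_epoch`` optionally
    subsamples the stream per epoch (desk-scale runs).  Returns the trained
    network and a history dict with per-epoch learning rate and losses.
    """
    X, Y = training if isinstance(training, tuple) else stack_pairs(training)
    if X.shape[0] == 0:
        raise ValueError("training set is empty")
    side = network.config.input_side
    if X.shape[2] != side or X.shape[3] != side:
        raise ValueError(f"training sections are {X.shape[2:]}, "
                         f"network expects {side}x{side}")
    if validation is not None:
        XV, YV = validation if isinstance(validation, tuple) else stack_pairs(validation)
    else:
        XV = YV = None

    rng = np.random.default_rng(config.seed)
    opt = nn.AdamW(network.params(), lr=config.base_lr,
                   weight_decay=config.weight_decay)
    a, b = config.tversky_alpha, config.tversky_beta
    history: dict = {"epoch": [], "lr": [], "train_loss": [], "val_loss": [],
                     "n_sections": int(X.shape[0])}

    for epoch, lr in enumerate(config.epoch_lrs()):
        opt.lr = lr
        order = rng.permutation(X.shape[0])
        if config.sections_per_epoch is not None:
            order = order[: config.sections_per_epoch]
        losses = []
        for start in range(0, order.size, config.batch_size):
            idx = order[start: start + config.batch_size]
            xb = X[idx]
            tb = one_hot(Y[idx], network.config.n_classes)
            p = network.forward(xb, train=True)
            loss, dp = tversky_loss_grad(p, tb, a, b, config.tversky_smooth)
            opt.zero_grad()
            network.backward(dp)
            opt.step()
            losses.append(loss)
        history["epoch"].append(epoch)
        history["lr"].append(lr)
        history["train_loss"].append(float(np.mean(losses)))
        if XV is not None and XV.shape[0]:
            history["val_loss"].append(
                evaluate_loss(network, XV, YV, a, b, config.batch_size))
        else:
            history["val_loss"].append(None)
    return network, history


def evaluate_loss(network: ScanningUNet, X: np.ndarray, Y: np.ndarray,
                  alpha: float, beta: float, batch_size: int = 8) -> float:
    """Mean Tversky loss over a section set in inference mode."""
    losses = []
    for start in range(0, X.shape[0], batch_size):
        xb = X[start: start + batch_size]
        tb = one_hot(Y[start: start + batch_size], network.config.n_classes)
        p = network.forward(xb, train=False)
        losses.append(tversky_loss(p, tb, alpha, beta))
    return float(np.mean(losses))


def predict_slices(network: ScanningUNet,
                   batch: SliceBatch | np.ndarray,
                   batch_size: int = 8) -> np.ndarray:
    """Per-section class probabilities (n, n_classes, H, W), order preserved."""
    slices = batch.slices if isinstance(batch, SliceBatch) else np.asarray(batch)
    if slices.shape[0] == 0:
        s = network.config.input_side
        return np.zeros((0, network.config.n_classes, s, s), dtype=F32)
    x = slices.astype(F32)
    if np.issubdtype(slices.dtype, np.integer):
        x /= F32(255.0)
    x = x[:, None]
    out = [network.forward(x[i: i + batch_size], train=False)
           for i in range(0, x.shape[0], batch_size)]
    return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(network: ScanningUNet, path: str | Path,
                    train_config: TrainConfig | None = None) -> None:
    """Weights + configs + seed in a single .npz file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"network_config": asdict(network.config),
            "train_config": asdict(train_config) if train_config else None,
            "seed": network.seed}
    arrays = {f"param_{i}": p.v for i, p in enumerate(network.params())}
    arrays.update({f"state_{i}": s for i, s in enumerate(network.state_arrays())})
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> tuple[ScanningUNet, dict]:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        network = ScanningUNet(NetworkConfig(**meta["network_config"]),
                               seed=meta.get("seed", 0))
        for i, p in enumerate(network.params()):
            p.v[...] = z[f"param_{i}"]
        for i, s in enumerate(network.state_arrays()):
            s[...] = z[f"state_{i}"]
    return network, meta
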