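"""Compact 2D encoder–decoder segmentation network, pure numpy.

Architecture: an input projection (3×3 conv + batch norm + ReLU), three
encoders (2×2 max-pool then 3×3 conv + BN + ReLU, doubling channel
width), three decoders (3×3 transposed conv with stride 2, concatenation
with the same-level encoder feature map over a skip connection, then
3×3 conv + BN + ReLU) and a 1×1 output projection producing per-pixel
class scores. Training minimizes pixel-wise softmax cross-entropy with
Adam, with random crop ("cut") and flip augmentation.

The network is deliberately small — it segments desk-scale phantom
slices so the full contour-evaluation workflow can run end-to-end on a
CPU in minutes. Forward and backward passes are hand-written (shifted-
slice convolutions); everything is a pure function of the seed, so
training is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grids import BinaryMask, StructureSet, VolumeGrid


@dataclass(frozen=True)
class NetworkSpec:
    in_channels: int = 1
    n_classes: int = 10
    channels: tuple[int, int, int] = (16, 32, 64)
    levels: int = 3  # encoder/decoder count; fixed by the architecture

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.levels != 3 or len(self.channels) != 3:
            raise ValueError("this architecture has exactly 3 encoder/decoder levels")


@dataclass
class TrainConfig:
    epochs: int = 60
    learning_rate: float = 2e-3
    batch_size: int = 4
    seed: int = 0
    augment: bool = True
    #: random-crop ("cut") size; None trains on full slices. Cropping
    #: discards absolute lateral position, which paired L/R structures
    #: need at this field of view, so the default is no cropping.
    crop: int | None = None
    intensity_scale: float = 125.0  # x -> x/scale - 1 normalization
    class_weighting: str = "median-frequency"  # or "none"
    #: label pairs exchanged under a lateral flip (left/right organs);
    #: default matches the canonical 9-structure labelling
    lateral_swap: tuple[tuple[int, int], ...] = ((3, 4), (6, 7))

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class ShapeError(ValueError):
    pass


def _check_divisible(h: int, w: int) -> None:
    if h % 8 or w % 8:
        raise ShapeError(
            f"spatial dims ({h}, {w}) must be divisible by 8 (three 2x poolings); "
            f"pad to ({-(-h // 8) * 8}, {-(-w // 8) * 8})"
        )


# ---------------------------------------------------------------------------
# primitives (N, C, H, W)


def _conv3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-size 3x3 stride-1 cross-correlation, zero padding 1."""
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((n, w.shape[0], h, wd), dtype=x.dtype)
    for i in range(3):
        for j in range(3):
            out += np.einsum("nchw,oc->nohw", xp[:, :, i:i + h, j:j + wd], w[:, :, i, j],
                             optimize=True)
    return out + b[None, :, None, None]


def _conv3_backward(x: np.ndarray, w: np.ndarray, dout: np.ndarray):
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dw = np.empty_like(w)
    for i in range(3):
        for j in range(3):
            dw[:, :, i, j] = np.einsum("nohw,nchw->oc", dout, xp[:, :, i:i + h, j:j + wd],
                                       optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    # gradient w.r.t. input: same conv of dout with channel-transposed, flipped kernel
    wf = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
    dx = _conv3(dout, np.ascontiguousarray(wf), np.zeros(wf.shape[0], dtype=w.dtype))
    return dx, dw, db


class Layer:
    params: dict
    grads: dict

    def forward(self, x, train):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3(Layer):
    def __init__(self, cin, cout, rng):
        scale = np.sqrt(2.0 / (cin * 9))
        self.params = {"w": rng.normal(0, scale, (cout, cin, 3, 3)),
                       "b": np.zeros(cout)}
        self.grads = {}

    def forward(self, x, train):
        self.x = x
        return _conv3(x, self.params["w"], self.params["b"])

    def backward(self, dout):
        dx, dw, db = _conv3_backward(self.x, self.params["w"], dout)
        self.grads = {"w": dw, "b": db}
        return dx


class Conv1(Layer):
    """1x1 convolution (the output pixel-classification projection)."""

    def __init__(self, cin, cout, rng):
        self.params = {"w": rng.normal(0, np.sqrt(2.0 / cin), (cout, cin)),
                       "b": np.zeros(cout)}
        self.grads = {}

    def forward(self, x, train):
        self.x = x
        return (np.einsum("nchw,oc->nohw", x, self.params["w"], optimize=True)
                + self.params["b"][None, :, None, None])

    def backward(self, dout):
        self.grads = {"w": np.einsum("nohw,nchw->oc", dout, self.x, optimize=True),
                      "b": dout.sum(axis=(0, 2, 3))}
        return np.einsum("nohw,oc->nchw", dout, self.params["w"], optimize=True)


class BatchNorm(Layer):
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.params = {"gamma": np.ones(c), "beta": np.zeros(c)}
        self.grads = {}
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self._last_mean, self._last_var = mean, var
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self.inv = 1.0 / np.sqrt(var + self.eps)
        self.xhat = (x - mean[None, :, None, None]) * self.inv[None, :, None, None]
        self.m = x.shape[0] * x.shape[2] * x.shape[3]
        return (self.params["gamma"][None, :, None, None] * self.xhat
                + self.params["beta"][None, :, None, None])

    def backward(self, dout):
        g = self.params["gamma"][None, :, None, None]
        self.grads = {"gamma": (dout * self.xhat).sum(axis=(0, 2, 3)),
                      "beta": dout.sum(axis=(0, 2, 3))}
        dxhat = dout * g
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - self.xhat * (dxhat * self.xhat).mean(axis=(0, 2, 3), keepdims=True))
        return dx * self.inv[None, :, None, None]


class ReLU(Layer):
    params: dict = {}
    grads: dict = {}

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x, train):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout):
        return dout * self.mask


class MaxPool2(Layer):
    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        # break ties toward a single winner to keep gradients exact
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        flat = flat & (np.cumsum(flat, axis=-1) == 1)
        self.argmask = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self.in_shape = x.shape
        return out

    def backward(self, dout):
        d = self.argmask * dout[:, :, :, None, :, None]
        return d.reshape(self.in_shape)


class ConvTranspose3(Layer):
    """3x3 transposed convolution, stride 2: doubles the spatial size."""

    def __init__(self, cin, cout, rng):
        scale = np.sqrt(2.0 / (cin * 9))
        self.params = {"w": rng.normal(0, scale, (cin, cout, 3, 3)),
                       "b": np.zeros(cout)}
        self.grads = {}

    def forward(self, x, train):
        self.x = x
        n, cin, h, wd = x.shape
        w = self.params["w"]
        outp = np.zeros((n, w.shape[1], 2 * h + 1, 2 * wd + 1), dtype=x.dtype)
        for i in range(3):
            for j in range(3):
                outp[:, :, i:i + 2 * h:2, j:j + 2 * wd:2] += np.einsum(
                    "nchw,co->nohw", x, w[:, :, i, j], optimize=True)
        out = outp[:, :, 1:, 1:]
        return out + self.params["b"][None, :, None, None]

    def backward(self, dout):
        x, w = self.x, self.params["w"]
        n, cin, h, wd = x.shape
        doutp = np.zeros((n, dout.shape[1], 2 * h + 1, 2 * wd + 1), dtype=dout.dtype)
        doutp[:, :, 1:, 1:] = dout
        dw = np.empty_like(w)
        dx = np.zeros_like(x)
        for i in range(3):
            for j in range(3):
                win = doutp[:, :, i:i + 2 * h:2, j:j + 2 * wd:2]
                dw[:, :, i, j] = np.einsum("nchw,nohw->co", x, win, optimize=True)
                dx += np.einsum("nohw,co->nchw", win, w[:, :, i, j], optimize=True)
        self.grads = {"w": dw, "b": dout.sum(axis=(0, 2, 3))}
        return dx


class _Block:
    """conv -> BN -> ReLU."""

    def __init__(self, cin, cout, rng):
        self.conv, self.bn, self.relu = Conv3(cin, cout, rng), BatchNorm(cout), ReLU()
        self.layers = [self.conv, self.bn, self.relu]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, d):
        for l in reversed(self.layers):
            d = l.backward(d)
        return d


class EncoderDecoder:
    """The segmentation model; see module docstring for the architecture."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        c0, c1, c2 = spec.channels
        self.in_proj = _Block(spec.in_channels, c0, rng)
        self.enc = [_Block(c0, c1, rng), _Block(c1, c2, rng), _Block(c2, c2, rng)]
        self.pools = [MaxPool2(), MaxPool2(), MaxPool2()]
        self.ups = [ConvTranspose3(c2, c2, rng), ConvTranspose3(c2, c1, rng),
                    ConvTranspose3(c1, c0, rng)]
        self.dec = [_Block(2 * c2, c2, rng), _Block(2 * c1, c1, rng), _Block(2 * c0, c0, rng)]
        self.out_proj = Conv1(c0, spec.n_classes, rng)
        self.trained = False

    # -- bookkeeping -------------------------------------------------------
    def _blocks(self):
        yield self.in_proj
        yield from self.enc
        yield from self.dec

    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for b in self._blocks():
            out.extend(b.layers)
        out.extend(self.ups)
        out.append(self.out_proj)
        return out

    def parameter_count(self) -> int:
        return sum(p.size for l in self.layers() for p in l.params.values())

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, 1, H, W) image -> (N, n_classes, H, W) class scores."""
        _check_divisible(x.shape[2], x.shape[3])
        s0 = self.in_proj.forward(x, train)
        s1 = self.enc[0].forward(self.pools[0].forward(s0, train), train)
        s2 = self.enc[1].forward(self.pools[1].forward(s1, train), train)
        bott = self.enc[2].forward(self.pools[2].forward(s2, train), train)
        skips = [s2, s1, s0]
        y = bott
        self._split = []
        for up, dec, skip in zip(self.ups, self.dec, skips):
            y = up.forward(y, train)
            self._split.append(skip.shape[1])
            y = dec.forward(np.concatenate([skip, y], axis=1), train)
        return self.out_proj.forward(y, train)

    def backward(self, dscores: np.ndarray) -> None:
        d = self.out_proj.backward(dscores)
        dskips = []
        for up, dec, csplit in zip(reversed(self.ups), reversed(self.dec),
                                   reversed(self._split)):
            d = dec.backward(d)
            dskip, d = d[:, :csplit], d[:, csplit:]
            d = up.backward(d)
            dskips.append(dskip)
        # dskips collected in order [s0, s1, s2]
        ds0, ds1, ds2 = dskips
        d = self.pools[2].backward(self.enc[2].backward(d))
        d = self.pools[1].backward(self.enc[1].backward(d + ds2))
        d = self.pools[0].backward(self.enc[0].backward(d + ds1))
        self.in_proj.backward(d + ds0)

    # -- persistence -------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, l in enumerate(self.layers()):
            for k, v in l.params.items():
                out[f"{i}:{k}"] = v
            if isinstance(l, BatchNorm):
                out[f"{i}:running_mean"] = l.running_mean
                out[f"{i}:running_var"] = l.running_var
        return out

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self.state_arrays())
        sidecar = {"n_classes": self.spec.n_classes, "in_channels": self.spec.in_channels,
                   "channels": list(self.spec.channels), "trained": self.trained}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "EncoderDecoder":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(NetworkSpec(in_channels=meta["in_channels"], n_classes=meta["n_classes"],
                                channels=tuple(meta["channels"])))
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
            for i, l in enumerate(model.layers()):
                for k in l.params:
                    l.params[k] = data[f"{i}:{k}"]
                if isinstance(l, BatchNorm):
                    l.running_mean = data[f"{i}:running_mean"]
                    l.running_var = data[f"{i}:running_var"]
        model.trained = meta.get("trained", False)
        return model


def softmax_cross_entropy(scores: np.ndarray, labels: np.ndarray,
                          class_weights: np.ndarray | None = None):
    """Pixel-wise softmax cross-entropy and its gradient w.r.t. scores.

    Optional per-class weights rebalance the loss when foreground classes
    occupy a tiny pixel fraction (weighted mean over pixels).
    """
    n, k, h, w = scores.shape
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in [0, {k}), got [{labels.min()}, {labels.max()}]")
    s = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(s)
    p = e / e.sum(axis=1, keepdims=True)
    idx = (np.arange(n)[:, None, None], labels,
           np.arange(h)[None, :, None], np.arange(w)[None, None, :])
    wpix = 1.0 if class_weights is None else class_weights[labels]
    wsum = n * h * w if class_weights is None else float(np.sum(wpix))
    loss = float(np.sum(wpix * -np.log(np.maximum(p[idx], 1e-12))) / wsum)
    dscores = p.copy()
    dscores[idx] -= 1.0
    if class_weights is not None:
        dscores = dscores * wpix[:, None]
    return loss, dscores / wsum


def median_frequency_weights(slices, n_classes: int) -> np.ndarray:
    """Median-frequency-balanced class weights from labelled slices.

    w_c = median(freq) / freq_c, capped at 50; absent classes get weight 0.
    Rebalances the loss so small organs are not dominated by background.
    """
    counts = np.zeros(n_classes)
    for _, lab in slices:
        counts += np.bincount(lab.ravel(), minlength=n_classes)[:n_classes]
    freq = counts / max(counts.sum(), 1)
    present = freq > 0
    med = np.median(freq[present])
    weights = np.zeros(n_classes)
    weights[present] = np.minimum(med / freq[present], 50.0)
    return weights


class Adam:
    def __init__(self, layers: list[Layer], lr: float):
        self.layers, self.lr = layers, lr
        self.b1, self.b2, self.eps, self.t = 0.9, 0.999, 1e-8, 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for l, m, v in zip(self.layers, self.m, self.v):
            for k, g in l.grads.items():
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g**2
                l.params[k] -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)


def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> EncoderDecoder:
    return EncoderDecoder(spec or NetworkSpec(), seed=seed)


def _augment(img, lab, rng, crop, lateral_swap):
    if rng.random() < 0.5:
        # lateral mirror: swap left/right organ labels along with the pixels
        img, lab = img[::-1], lab[::-1].copy()
        for a, b in lateral_swap:
            ma, mb = lab == a, lab == b
            lab[ma], lab[mb] = b, a
    if crop is not None and img.shape[0] > crop and img.shape[1] > crop:
        oy = rng.integers(0, img.shape[0] - crop + 1)
        ox = rng.integers(0, img.shape[1] - crop + 1)
        img, lab = img[oy:oy + crop, ox:ox + crop], lab[oy:oy + crop, ox:ox + crop]
    return img, lab


def train(model: EncoderDecoder, slices: list[tuple[np.ndarray, np.ndarray]],
          config: TrainConfig | None = None) -> list[float]:
    """Train on labelled 2D slices; returns the per-epoch mean loss trace.

    *slices* is a list of (image (H, W) float, labels (H, W) int) pairs.
    Deterministic for a given config seed. Raises if the loss diverges or
    the final epoch fails to improve on the first.
    """
    config = config or TrainConfig()
    if len(slices) < 10:
        raise ValueError(f"need at least 10 labelled slices, got {len(slices)}")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.layers(), config.learning_rate)
    weights = None
    if config.class_weighting == "median-frequency":
        weights = median_frequency_weights(slices, model.spec.n_classes)
    elif config.class_weighting != "none":
        raise ValueError(f"unknown class_weighting {config.class_weighting!r}")
    trace: list[float] = []
    n = len(slices)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            imgs, labs = [], []
            for b in batch:
                img, lab = slices[b]
                if config.augment:
                    img, lab = _augment(img, lab, rng, config.crop, config.lateral_swap)
                imgs.append(img / config.intensity_scale - 1.0)
                labs.append(lab)
            x = np.stack(imgs)[:, None].astype(float)
            y = np.stack(labs).astype(int)
            scores = model.forward(x, train=True)
            loss, dscores = softmax_cross_entropy(scores, y, weights)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (loss={loss}); config: {config}")
            model.backward(dscores)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    if trace[-1] >= trace[0]:
        raise RuntimeError("training failed to reduce the loss; adjust the config")
    _recalibrate_batchnorm(model, slices, config)
    model.trained = True
    model.intensity_scale = config.intensity_scale
    return trace


def _recalibrate_batchnorm(model: EncoderDecoder, slices, config: TrainConfig) -> None:
    """Reset BN running statistics from full-size, un-augmented slices.

    Training sees augmented crops whose feature statistics differ from the
    full slices used at inference; a final estimation sweep removes that
    mismatch. Means/variances are averaged over batches exactly (no
    exponential smoothing).
    """
    bns = [l for l in model.layers() if isinstance(l, BatchNorm)]
    collected: dict[int, list] = {id(bn): [] for bn in bns}
    for start in range(0, len(slices), config.batch_size):
        batch = slices[start:start + config.batch_size]
        x = np.stack([img / config.intensity_scale - 1.0 for img, _ in batch])[:, None]
        model.forward(x.astype(float), train=True)
        for bn in bns:
            collected[id(bn)].append((bn._last_mean, bn._last_var))
    for bn in bns:
        means = np.stack([m for m, _ in collected[id(bn)]])
        varis = np.stack([v for _, v in collected[id(bn)]])
        bn.running_mean = means.mean(axis=0)
        bn.running_var = varis.mean(axis=0) + means.var(axis=0)


def segment(model: EncoderDecoder, image: VolumeGrid,
            structure_names: list[str]) -> StructureSet:
    """Per-slice argmax segmentation of a 3D image, assembled into a StructureSet.

    Class k (k > 0) maps to structure_names[k-1]; class 0 is background.
    """
    if not getattr(model, "trained", False):
        raise RuntimeError("model has not been trained")
    scale = getattr(model, "intensity_scale", TrainConfig().intensity_scale)
    geom = image.geometry
    labels = np.zeros(geom.shape, dtype=np.int16)
    for k in range(geom.shape[2]):
        x = (image.values[:, :, k] / scale - 1.0)[None, None].astype(float)
        scores = model.forward(x, train=False)
        labels[:, :, k] = np.argmax(scores[0], axis=0)
    structures = {name: BinaryMask(geom, labels == i + 1)
                  for i, name in enumerate(structure_names)}
    return StructureSet(structures, provenance="auto")
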