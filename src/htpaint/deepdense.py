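"""DeepSTORM-style density-map network for high-density SMLM frames.

A fully convolutional encoder-decoder maps a camera frame (bilinearly resized
to the upsampled super-resolution grid) to a nonnegative localization-density
map on that grid.  Training minimizes a Gaussian-blurred mean-squared error
between the predicted map and a spike map of the true emitter positions, plus
an L1 sparsity penalty; localizations are then extracted from predicted maps
by thresholded local-maximum search with intensity-weighted local averaging,
and the threshold is calibrated against a reference localization count.

The network, its training loop (Adam with plateau-based learning-rate
reduction) and the extraction/calibration logic are implemented here directly
on numpy arrays; layers use the channels-last (batch, height, width,
channel) layout with numba kernels for the 3x3 convolutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import FrameStack, LocalizationTable, substream
from .densitydata import TrainingPatchSet, center_crop, make_label_maps

# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Conv2d:
    """3x3 (numba kernel) or 1x1 (GEMM) convolution, channels-last, He init."""

    def __init__(self, c_in, c_out, k, rng):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = (rng.standard_normal((k, k, c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k = k

    def forward(self, x, training):
        from ._nnops import conv3x3_fwd
        self.x = x if training else None
        if self.k == 1:
            B, H, Wd, _ = x.shape
            return (x.reshape(-1, x.shape[-1]) @ self.W[0, 0] + self.b).reshape(
                B, H, Wd, -1)
        y = np.empty(x.shape[:3] + (self.W.shape[3],), dtype=np.float32)
        conv3x3_fwd(np.ascontiguousarray(x), self.W, self.b, y)
        return y

    def backward(self, dy):
        from ._nnops import conv3x3_dw, conv3x3_fwd
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        if self.k == 1:
            flat_x = self.x.reshape(-1, self.x.shape[-1])
            flat_dy = dy.reshape(-1, dy.shape[-1])
            self.dW[0, 0] = flat_x.T @ flat_dy
            self.db[:] = flat_dy.sum(axis=0)
            dx = (flat_dy @ self.W[0, 0].T).reshape(self.x.shape)
            self.x = None
            return dx
        x = np.ascontiguousarray(self.x)
        conv3x3_dw(x, dy, self.dW, self.db)
        # dx = dy convolved with spatially flipped, channel-transposed weights
        Wrot = np.ascontiguousarray(self.W[::-1, ::-1].transpose(0, 1, 3, 2))
        dx = np.empty_like(x)
        conv3x3_fwd(dy, Wrot, np.zeros(x.shape[-1], dtype=np.float32), dx)
        self.x = None
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm2d:
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    @staticmethod
    def _channel_sums(x2d):
        # ones-vector matmul: much faster than reductions over leading axes
        ones = np.ones(x2d.shape[0], dtype=np.float32)
        return ones @ x2d, ones @ (x2d * x2d)

    def forward(self, x, training):
        if training:
            n = x.size // x.shape[-1]
            s1, s2 = self._channel_sums(x.reshape(-1, x.shape[-1]))
            mean = s1 / n
            var = np.maximum(s2 / n - mean * mean, 0.0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self.inv_std = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
            self.xhat = (x - mean) * self.inv_std
            return self.gamma * self.xhat + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma * ((x - self.running_mean) * inv) + self.beta

    def backward(self, dy):
        c = dy.shape[-1]
        n = dy.size // c
        ones = np.ones(n, dtype=np.float32)
        dy2d = dy.reshape(-1, c)
        xhat2d = self.xhat.reshape(-1, c)
        self.dbeta[:] = ones @ dy2d
        self.dgamma[:] = (ones @ (dy2d * xhat2d))
        g = self.gamma * self.inv_std
        mean_dy = self.dbeta / n
        mean_dy_xhat = self.dgamma / n
        dx = g * (dy - mean_dy - self.xhat * mean_dy_xhat)
        self.xhat = None
        return dx.astype(np.float32)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ReLU:
    def forward(self, x, training):
        if training:
            self.mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        out = dy * self.mask
        self.mask = None
        return out

    def params(self):
        return []


class MaxPool2:
    def forward(self, x, training):
        B, H, W, C = x.shape
        a = x.reshape(B, H // 2, 2, W // 2, 2, C)
        y = a.max(axis=4).max(axis=2)
        if training:
            # winner mask; a rare within-window tie duplicates the gradient,
            # which is harmless for SGD
            self.mask = a == y[:, :, None, :, None, :]
            self.in_shape = x.shape
        return y

    def backward(self, dy):
        B, H, W, C = self.in_shape
        a = dy[:, :, None, :, None, :] * self.mask
        self.mask = None
        return a.reshape(B, H, W, C)

    def params(self):
        return []


class Softplus:
    """Smooth nonnegative output activation, log(1 + e^x).

    Preferred over a final ReLU: a ReLU output head dies wherever its
    pre-activation is non-positive (gradient exactly zero), which freezes
    large zero regions of the sparse density map at initialization; softplus
    keeps a nonvanishing gradient everywhere while the map stays >= 0.
    """

    def forward(self, x, training):
        if training:
            self.x = x
        return np.logaddexp(0.0, x).astype(np.float32)

    def backward(self, dy):
        sig = 1.0 / (1.0 + np.exp(-self.x))
        self.x = None
        return (dy * sig).astype(np.float32)

    def params(self):
        return []


class Upsample2:
    def forward(self, x, training):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        B, H, W, C = dy.shape
        return dy.reshape(B, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))

    def params(self):
        return []


class Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training hyperparameters for the density-map network.

    The fidelity profile matches the published workflow (upsampling 16 for
    fixed cells / 8 for live cells, batch 256, 100 epochs, 15 % validation
    split, initial learning rate 1e-5); :func:`desk_config` provides the
    reduced desk-scale profile.
    """

    upsampling: int = 16
    batch_size: int = 256
    epochs: int = 100
    val_split: float = 0.15
    learning_rate: float = 1e-5
    loss_blur_sigma_px: float = 2.0   # on the upsampled grid
    l1_weight: float = 1e-2
    seed: int = 0
    widths: tuple = (4, 8, 16)
    spike_amplitude: float = 10.0
    crop_px: int = 16
    lr_patience: int = 10
    lr_factor: float = 0.5
    min_lr_fraction: float = 0.01

    def __post_init__(self):
        if not 0 < self.val_split < 1:
            raise ValueError("val_split must be in (0, 1)")
        if self.upsampling < 1:
            raise ValueError("upsampling must be >= 1")


def desk_config(upsampling: int = 8, seed: int = 0) -> TrainConfig:
    """Reduced desk-scale training profile: 20 epochs, batch 64, lr 1e-2.

    Intended for ~2,000 patches on a single CPU; the narrow network and the
    short schedule call for a much larger step size than the fidelity
    profile.  The fidelity profile (:class:`TrainConfig` defaults) remains
    the reference setting.
    """
    return TrainConfig(upsampling=upsampling, batch_size=16, epochs=20,
                       learning_rate=1e-2, seed=seed)


@dataclass
class TrainedModel:
    """Encoder-decoder network plus its input-normalization statistics."""

    layers: list
    config: TrainConfig
    norm_mean: float = 0.0
    norm_std: float = 1.0
    history: dict = field(default_factory=lambda: {"train_loss": [], "val_loss": [], "lr": []})

    @property
    def upsampling(self) -> int:
        return self.config.upsampling

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def parameters(self) -> list:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


def build_model(config: TrainConfig) -> TrainedModel:
    """Untrained encoder-decoder: 3 conv+BN+ReLU+pool blocks, mirrored
    upsample+conv blocks, final 1x1 conv with softplus (nonnegative output).

    Fully convolutional: the parameter count is independent of input size, so
    a model trained on 16 px patches predicts whole camera frames.
    """
    rng = substream(config.seed, "init")
    c1, c2, c3 = config.widths
    layers = [
        Conv2d(1, c1, 3, rng), BatchNorm2d(c1), ReLU(), MaxPool2(),
        Conv2d(c1, c2, 3, rng), BatchNorm2d(c2), ReLU(), MaxPool2(),
        Conv2d(c2, c3, 3, rng), BatchNorm2d(c3), ReLU(), MaxPool2(),
        Upsample2(), Conv2d(c3, c2, 3, rng), BatchNorm2d(c2), ReLU(),
        Upsample2(), Conv2d(c2, c1, 3, rng), BatchNorm2d(c1), ReLU(),
        Upsample2(), Conv2d(c1, c1, 3, rng), BatchNorm2d(c1), ReLU(),
        Conv2d(c1, 1, 1, rng), Softplus(),
    ]
    # start the softplus head near zero output so the sparse background does
    # not have to be unlearned from the softplus(0) = log 2 floor
    layers[-2].b[:] = -2.0
    return TrainedModel(layers=layers, config=config)


def _bilinear_resize_batch(images: np.ndarray, u: int) -> np.ndarray:
    """Bilinear upsample (n, H, W) -> (n, H*u, W*u) on aligned grids."""
    out = np.empty((images.shape[0], images.shape[1] * u, images.shape[2] * u),
                   dtype=np.float32)
    for i in range(images.shape[0]):
        out[i] = ndimage.zoom(images[i].astype(np.float32), u, order=1,
                              mode="nearest", grid_mode=True)
    return out


def _gaussian_kernel1d(sigma: float) -> np.ndarray:
    r = max(1, int(round(3 * sigma)))
    t = np.arange(-r, r + 1)
    k = np.exp(-t * t / (2.0 * sigma * sigma))
    return (k / k.sum()).astype(np.float32)


class _BlurredMSELoss:
    """MSE between Gaussian-blurred prediction and blurred spike map, plus an
    L1 sparsity penalty on the raw prediction.  The blur kernel is symmetric,
    so the adjoint in the gradient is the same convolution."""

    def __init__(self, sigma_px: float, l1_weight: float):
        self.k = _gaussian_kernel1d(sigma_px)
        self.l1 = l1_weight

    def _blur(self, x):
        y = ndimage.convolve1d(x, self.k, axis=1, mode="constant")
        return ndimage.convolve1d(y, self.k, axis=2, mode="constant")

    def value_and_grad(self, pred, target):
        diff = self._blur(pred - target)
        n = diff.size
        loss = float((diff ** 2).mean() + self.l1 * np.abs(pred).mean())
        grad = (2.0 / n) * self._blur(diff) + (self.l1 / n) * np.sign(pred)
        return loss, grad.astype(np.float32)

    def value(self, pred, target):
        diff = self._blur(pred - target)
        return float((diff ** 2).mean() + self.l1 * np.abs(pred).mean())


def train(model: TrainedModel, patch_set: TrainingPatchSet,
          config: TrainConfig | None = None, verbose: bool = False) -> TrainedModel:
    """Train the density-map network on summed high-density patches.

    Patches are center-cropped to ``crop_px`` (17 -> 16 by default), spike
    label maps are built on the upsampled grid, inputs are standardized by the
    training-set mean/std (stored in the model for prediction), a
    ``val_split`` fraction is held out, and Adam minimizes the blurred-MSE +
    L1 loss with plateau-based learning-rate reduction.
    """
    cfg = config or model.config
    if len(patch_set) == 0:
        raise ValueError("empty patch set")
    if patch_set.patch_px != cfg.crop_px:
        patch_set = center_crop(patch_set, cfg.crop_px)
    u = cfg.upsampling
    images = patch_set.patches.astype(np.float32)
    targets = make_label_maps(patch_set, u, amplitude=cfg.spike_amplitude)

    model.norm_mean = float(images.mean())
    model.norm_std = float(images.std()) or 1.0
    images = (images - model.norm_mean) / model.norm_std
    inputs = _bilinear_resize_batch(images, u)[..., None]  # (n,Pu,Pu,1)
    targets = targets[..., None]

    rng = substream(cfg.seed, "train")
    n = len(inputs)
    n_val = int(round(cfg.val_split * n))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    loss_fn = _BlurredMSELoss(cfg.loss_blur_sigma_px, cfg.l1_weight)
    opt = Adam(model.parameters(), cfg.learning_rate)
    best_val, stale = np.inf, 0

    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        ep_loss, n_batches = 0.0, 0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            pred = model.forward(inputs[idx], training=True)
            loss, grad = loss_fn.value_and_grad(pred, targets[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            model.backward(grad)
            opt.step()
            ep_loss += loss
            n_batches += 1
        val_loss = 0.0
        if len(val_idx):
            for lo in range(0, len(val_idx), cfg.batch_size):
                idx = val_idx[lo:lo + cfg.batch_size]
                pred = model.forward(inputs[idx], training=False)
                val_loss += loss_fn.value(pred, targets[idx]) * len(idx)
            val_loss /= len(val_idx)
        model.history["train_loss"].append(ep_loss / max(n_batches, 1))
        model.history["val_loss"].append(val_loss)
        model.history["lr"].append(opt.lr)
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs}: train {ep_loss / max(n_batches, 1):.5g} "
                  f"val {val_loss:.5g} lr {opt.lr:.2g}")
        if val_loss < best_val - 1e-12:
            best_val, stale = val_loss, 0
        else:
            stale += 1
            if stale >= cfg.lr_patience:
                opt.lr = max(opt.lr * cfg.lr_factor,
                             cfg.learning_rate * cfg.min_lr_fraction)
                stale = 0
    return model


# ---------------------------------------------------------------------------
# prediction and localization extraction
# ---------------------------------------------------------------------------

@dataclass
class PredictionMap:
    """Per-frame upsampled localization-density map."""

    data: np.ndarray
    upsampling: int
    frame_index: int
    threshold: float | None = None

    def __post_init__(self):
        if np.any(self.data < 0):
            raise ValueError("prediction map must be nonnegative")


def predict(model: TrainedModel, stack, camera=None, batch_size: int = 1) -> list:
    """Per-frame density-map prediction on an (optionally drift-corrected)
    high-density stack.

    ``stack`` may be a FrameStack (frames are photon-converted through its
    camera) or an (n, H, W) array already in photon units.  Inputs are
    standardized with the statistics stored at training time; maps are
    deterministic given the weights.
    """
    if isinstance(stack, FrameStack):
        frames = stack.photons()
    else:
        frames = np.asarray(stack, dtype=np.float32)
        if camera is not None:
            frames = camera.adu_to_photons(frames)
    if frames.ndim == 2:
        frames = frames[None]
    u = model.upsampling
    frames = (frames.astype(np.float32) - model.norm_mean) / model.norm_std
    maps = []
    for lo in range(0, len(frames), max(batch_size, 1)):
        batch = _bilinear_resize_batch(frames[lo:lo + max(batch_size, 1)], u)
        B, H, W = batch.shape
        ph = (-H) % 8
        pw = (-W) % 8
        if ph or pw:  # pooling needs multiples of 8; pad then crop back
            batch = np.pad(batch, ((0, 0), (0, ph), (0, pw)), mode="symmetric")
        out = model.forward(batch[..., None], training=False)[..., 0]
        out = out[:, :H, :W]
        for k in range(B):
            maps.append(PredictionMap(data=out[k].copy(), upsampling=u,
                                      frame_index=lo + k))
    return maps


def _map_maxima(data: np.ndarray, threshold: float):
    """Strict local maxima (3x3) at or above threshold.

    The center must exceed all eight neighbors: saturated plateaus (regions
    of exactly equal values, which a flat network response can produce over
    dense structure) yield no maxima instead of one per pixel.
    """
    footprint = np.ones((3, 3), bool)
    footprint[1, 1] = False
    mx = ndimage.maximum_filter(data, footprint=footprint, mode="constant")
    mask = (data > mx) & (data >= threshold) & (data > 0)
    rows, cols = np.nonzero(mask)
    return rows, cols, data[rows, cols]


def maxima_values(maps: list) -> np.ndarray:
    """All local-maximum amplitudes across maps (calibration support)."""
    vals = [_map_maxima(m.data, 0.0)[2] for m in maps]
    return np.concatenate(vals) if vals else np.empty(0)


def calibrate_threshold(maps: list, reference_count: float, tolerance: float = 0.02,
                        max_steps: int = 60) -> float:
    """Bisect the extraction threshold to match a reference localization count.

    The number of extracted localizations is non-increasing in the threshold,
    so bisection converges; the search stops when the total count across all
    maps is within ``tolerance`` (relative) of ``reference_count``.  If even a
    zero threshold yields fewer localizations than the reference, 0 is
    returned with a warning.
    """
    if reference_count <= 0:
        raise ValueError("reference_count must be > 0")
    vals = maxima_values(maps)
    count = lambda t: int(np.count_nonzero(vals >= t))
    if count(0.0) < reference_count:
        warnings.warn("reference count unattainable even at threshold 0")
        return 0.0
    lo, hi = 0.0, float(vals.max()) if len(vals) else 1.0
    best_t, best_err = lo, abs(count(lo) - reference_count)
    for _ in range(max_steps):
        mid = 0.5 * (lo + hi)
        c = count(mid)
        err = abs(c - reference_count)
        if err < best_err:
            best_t, best_err = mid, err
        if err <= tolerance * reference_count:
            return mid
        if c > reference_count:
            lo = mid
        else:
            hi = mid
    return best_t


def extract_localizations(maps: list, threshold: float, neighborhood: int = 3,
                          local_averaging: bool = True,
                          pixel_size_nm: float = 157.0) -> LocalizationTable:
    """Extract a localization table from thresholded prediction maps.

    Each local maximum at or above the threshold yields one localization; with
    local averaging its position is the intensity-weighted centroid over the
    ``neighborhood`` x ``neighborhood`` window and its photon count is the
    window mass.  Map-grid positions are converted to camera-pixel units by
    dividing by the upsampling factor.
    """
    if neighborhood % 2 == 0:
        raise ValueError("neighborhood must be odd")
    h = neighborhood // 2
    rows_all = []
    for m in maps:
        r, c, v = _map_maxima(m.data, threshold)
        if len(r) == 0:
            continue
        u = m.upsampling
        if local_averaging:
            Hm, Wm = m.data.shape
            off = np.arange(-h, h + 1)
            rr = np.clip(r[:, None, None] + off[None, :, None], 0, Hm - 1)
            cc = np.clip(c[:, None, None] + off[None, None, :], 0, Wm - 1)
            win = m.data[rr, cc]
            mass = win.sum(axis=(1, 2))
            mass = np.where(mass > 0, mass, 1.0)
            rcent = (win.sum(axis=2) * (r[:, None] + off[None, :])).sum(axis=1) / mass
            ccent = (win.sum(axis=1) * (c[:, None] + off[None, :])).sum(axis=1) / mass
            photons = win.sum(axis=(1, 2))
        else:
            rcent, ccent, photons = r.astype(float), c.astype(float), v
        x = (ccent + 0.5) / u
        y = (rcent + 0.5) / u
        rows_all.append(dict(frame=np.full(len(r), m.frame_index), x=x, y=y,
                             photons=photons))
    if not rows_all:
        return LocalizationTable.from_arrays(pixel_size_nm=pixel_size_nm,
                                             source="deepdense")
    u = maps[0].upsampling
    cat = {k: np.concatenate([d[k] for d in rows_all]) for k in rows_all[0]}
    # grid-resolution placeholders for width/precision columns: the network
    # emits density maps, not per-spot PSF fits
    return LocalizationTable.from_arrays(pixel_size_nm=pixel_size_nm, source="deepdense",
                                         sx=1.0 / u, sy=1.0 / u, lpx=0.5 / u, lpy=0.5 / u,
                                         bg=0.0, **cat)
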