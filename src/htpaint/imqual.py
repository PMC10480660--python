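"""Image-quality assessment for super-resolution reconstructions.

Predicted reconstructions are referenced against a ground-truth render: both
are blurred (2 px Gaussian), min-max scaled to 8-bit, optionally restricted to
an Otsu foreground mask, and compared with Pearson correlation, SSIM, MS-SSIM,
mean absolute error and PSNR.  Spatial resolution is estimated parameter-free
by image decorrelation analysis: the cutoff frequency is located from the
correlation between the image spectrum and its phase-normalized, low-pass
masked version, swept over radial masks and Gaussian high-pass pre-filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.metrics import structural_similarity
from skimage.morphology import closing, disk


@dataclass
class MetricReport:
    """Similarity metrics for a ground-truth / prediction image pair."""

    pcc: float
    ssim: float
    ms_ssim: float
    mae: float
    psnr_db: float
    resolution_gt_nm: float | None = None
    resolution_pred_nm: float | None = None
    preprocessing: dict = field(default_factory=dict)

    def __post_init__(self):
        if not -1.0 - 1e-9 <= self.pcc <= 1.0 + 1e-9:
            raise ValueError("pcc out of [-1, 1]")
        if self.mae < 0:
            raise ValueError("mae must be >= 0")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("pcc", "ssim", "ms_ssim", "mae", "psnr_db",
                 "resolution_gt_nm", "resolution_pred_nm", "preprocessing")}


@dataclass
class ResolutionEstimate:
    """Decorrelation-analysis resolution estimate."""

    resolution_nm: float
    cutoff_frequency: float  # normalized (0, 1], 1 = Nyquist of the grid
    curves: np.ndarray       # (n_filters + 1, n_radii) decorrelation values
    radii: np.ndarray
    rendered_pixel_nm: float
    resolved: bool = True


def preprocess_pair(gt_image: np.ndarray, pred_image: np.ndarray,
                    blur_sigma_px: float = 2.0):
    """Blur both images (sigma 2 px) and min-max quantize them to 8-bit.

    Images must share a shape (resample the prediction onto the ground-truth
    grid first if the upsampling factors differ).
    """
    if gt_image.shape != pred_image.shape:
        raise ValueError("images must have equal shapes")
    return (_to_uint8(ndimage.gaussian_filter(np.asarray(gt_image, float), blur_sigma_px)),
            _to_uint8(ndimage.gaussian_filter(np.asarray(pred_image, float), blur_sigma_px)))


def _to_uint8(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        warnings.warn("constant image maps to all zeros in 8-bit conversion")
        return np.zeros(img.shape, dtype=np.uint8)
    return np.round((img - lo) / (hi - lo) * 255.0).astype(np.uint8)


def make_mask(gt8: np.ndarray, closing_radius: int = 2) -> np.ndarray:
    """Foreground mask of the labeled structure: Otsu threshold on the
    blurred 8-bit ground truth, then morphological closing."""
    gt8 = np.asarray(gt8)
    if gt8.max() == gt8.min():
        mask = np.ones(gt8.shape, dtype=bool)
    else:
        mask = gt8 > threshold_otsu(gt8)
    if closing_radius > 0:
        mask = closing(mask, disk(closing_radius))
    if not mask.any():
        raise ValueError("empty foreground mask")
    return mask


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


_MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


def _ssim_and_cs(a: np.ndarray, b: np.ndarray, data_range: float = 255.0,
                 sigma: float = 1.5, win_size: int = 11):
    """Mean SSIM and mean contrast-structure term with a Gaussian window."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    trunc = ((win_size - 1) / 2 - 0.5) / sigma
    f = lambda x: ndimage.gaussian_filter(x, sigma, truncate=trunc)
    K1, K2 = 0.01, 0.03
    C1, C2 = (K1 * data_range) ** 2, (K2 * data_range) ** 2
    mu_a, mu_b = f(a), f(b)
    va = f(a * a) - mu_a * mu_a
    vb = f(b * b) - mu_b * mu_b
    cov = f(a * b) - mu_a * mu_b
    cs_map = (2 * cov + C2) / (va + vb + C2)
    l_map = (2 * mu_a * mu_b + C1) / (mu_a ** 2 + mu_b ** 2 + C1)
    pad = (win_size - 1) // 2
    crop = (slice(pad, -pad or None), slice(pad, -pad or None))
    return float((l_map * cs_map)[crop].mean()), float(cs_map[crop].mean())


def ms_ssim(a: np.ndarray, b: np.ndarray, data_range: float = 255.0,
            weights: tuple = _MSSSIM_WEIGHTS) -> float:
    """Multiscale SSIM with the canonical 5-scale weights.

    Contrast-structure terms from every scale and the luminance-weighted SSIM
    from the coarsest scale are combined as a weighted geometric mean; images
    are downsampled 2x (average pooling) between scales.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n_scales = len(weights)
    min_side = min(a.shape)
    usable = min(n_scales, max(1, int(np.log2(min_side / 11)) + 1))
    vals = []
    for s in range(usable):
        ssim_s, cs_s = _ssim_and_cs(a, b, data_range)
        vals.append(ssim_s if s == usable - 1 else cs_s)
        if s < usable - 1:
            a = _downsample2(a)
            b = _downsample2(b)
    w = np.asarray(weights[:usable])
    w = w / w.sum()
    vals = np.clip(vals, 1e-9, None)
    return float(np.prod(vals ** w))


def _downsample2(img: np.ndarray) -> np.ndarray:
    H, W = img.shape
    img = img[:H - H % 2, :W - W % 2]
    return 0.25 * (img[0::2, 0::2] + img[1::2, 0::2] + img[0::2, 1::2] + img[1::2, 1::2])


def similarity_metrics(gt8: np.ndarray, pred8: np.ndarray,
                       mask: np.ndarray | None = None) -> MetricReport:
    """PCC / SSIM / MS-SSIM / MAE / PSNR between 8-bit image pairs.

    PCC and MAE are restricted to ``mask`` when given; SSIM variants are
    windowed and computed on the full frame.  A zero-MSE pair reports PSNR as
    +inf.
    """
    gt8 = np.asarray(gt8)
    pred8 = np.asarray(pred8)
    if gt8.shape != pred8.shape:
        raise ValueError("images must have equal shapes")
    sel = (mask.astype(bool).ravel() if mask is not None
           else np.ones(gt8.size, dtype=bool))
    g = gt8.ravel()[sel].astype(np.float64)
    p = pred8.ravel()[sel].astype(np.float64)
    pcc = pearson(g, p)
    ssim_val = float(structural_similarity(gt8, pred8, data_range=255,
                                           gaussian_weights=True, sigma=1.5,
                                           use_sample_covariance=False))
    ms = ms_ssim(gt8, pred8)
    mae = float(np.abs(g - p).mean())
    mse = float(((g - p) ** 2).mean())
    psnr = float("inf") if mse == 0 else float(10.0 * np.log10(255.0 ** 2 / mse))
    return MetricReport(pcc=pcc, ssim=ssim_val, ms_ssim=ms, mae=mae, psnr_db=psnr,
                        preprocessing=dict(masked=mask is not None))


def _apodize(img: np.ndarray, edge_fraction: float = 0.1) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    img = img - img.mean()
    win = [np.ones(s) for s in img.shape]
    for ax, s in enumerate(img.shape):
        n_edge = max(2, int(edge_fraction * s))
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_edge) / n_edge))
        w = np.ones(s)
        w[:n_edge] = ramp
        w[-n_edge:] = ramp[::-1]
        win[ax] = w
    return img * np.outer(win[0], win[1])


def decorrelation_resolution(image: np.ndarray, rendered_pixel_nm: float,
                             n_radii: int = 50, n_filters: int = 10) -> ResolutionEstimate:
    """Parameter-free resolution estimate by image decorrelation analysis.

    The edge-apodized image is Fourier transformed (I) and phase-normalized
    (In = I/|I|).  For radii r in (0, 1] the decorrelation d(r) is the
    normalized cross-correlation between I and In restricted to |k| < r.  The
    sweep is repeated for ``n_filters`` Gaussian high-pass pre-filtered
    copies; the cutoff is the highest local-maximum frequency over all
    curves and resolution = 2 * pixel size / cutoff.
    """
    img = _apodize(image)
    F = np.fft.fftshift(np.fft.fft2(img))
    absF = np.abs(F)
    Fn = np.where(absF > 0, F / np.where(absF > 0, absF, 1.0), 0.0)
    ky = np.fft.fftshift(np.fft.fftfreq(img.shape[0])) * 2.0
    kx = np.fft.fftshift(np.fft.fftfreq(img.shape[1])) * 2.0
    kr = np.hypot(*np.meshgrid(ky, kx, indexing="ij"))
    radii = np.linspace(1.0 / n_radii, 1.0, n_radii)

    # Gaussian high-pass strengths, geometrically spaced in real-space sigma
    sigmas = np.geomspace(image.shape[0] / 4, 1.0, n_filters) if n_filters else []
    curves = np.empty((n_filters + 1, n_radii))
    cross = F * np.conj(Fn)
    for fi in range(n_filters + 1):
        if fi == 0:
            Ff = F
        else:
            lowpass = np.exp(-kr ** 2 * (np.pi * sigmas[fi - 1] / 2.0) ** 2 / 4.0)
            Ff = F * (1.0 - lowpass)
        normF = np.sqrt((np.abs(Ff) ** 2).sum())
        cf = Ff * np.conj(Fn)
        for ri, r in enumerate(radii):
            m = kr < r
            denom = normF * np.sqrt(np.count_nonzero(m & (absF > 0)))
            curves[fi, ri] = (cf[m].real.sum() / denom) if denom > 0 else 0.0

    best_freq, found = 0.0, False
    for fi in range(n_filters + 1):
        d = curves[fi]
        peaks = [ri for ri in range(1, n_radii - 1)
                 if d[ri] >= d[ri - 1] and d[ri] > d[ri + 1] and d[ri] > 0.05]
        # a curve still rising at Nyquist peaks at the last radius
        if d[-1] > d[-2] and d[-1] > 0.05:
            peaks.append(n_radii - 1)
        if peaks:
            found = True
            f_peak = radii[max(peaks, key=lambda ri: d[ri])]
            best_freq = max(best_freq, float(f_peak))
    if not found or best_freq <= 0:
        warnings.warn("no decorrelation maximum found; image unresolved")
        return ResolutionEstimate(resolution_nm=float("inf"), cutoff_frequency=1e-6,
                                  curves=curves, radii=radii,
                                  rendered_pixel_nm=rendered_pixel_nm, resolved=False)
    return ResolutionEstimate(resolution_nm=2.0 * rendered_pixel_nm / best_freq,
                              cutoff_frequency=best_freq, curves=curves, radii=radii,
                              rendered_pixel_nm=rendered_pixel_nm)


def frame_sweep(maps: list, gt_render: np.ndarray, frame_counts: list,
                rendered_pixel_nm: float, threshold_reference: float,
                render_shape: tuple, oversampling: int,
                use_mask: bool = False) -> pd.DataFrame:
    """Prediction quality as a function of the number of input frames.

    For each count k, localizations are extracted from the first k prediction
    maps (threshold re-calibrated to the frame-scaled reference count),
    rendered, and compared with the ground-truth render.  Returns a tidy
    frame with one row per k.
    """
    from .deepdense import calibrate_threshold, extract_localizations
    from .locfit import render_locs

    rows = []
    n_total = len(maps)
    for k in frame_counts:
        if k > n_total:
            raise ValueError(f"frame count {k} exceeds available maps ({n_total})")
        sub = maps[:k]
        ref_k = threshold_reference * k / n_total
        thr = calibrate_threshold(sub, ref_k)
        table = extract_localizations(sub, thr)
        img = render_locs(table, oversampling=oversampling, shape=render_shape)
        gt8, pred8 = preprocess_pair(gt_render, img)
        mask = make_mask(gt8) if use_mask else None
        rep = similarity_metrics(gt8, pred8, mask)
        res = decorrelation_resolution(pred8.astype(float), rendered_pixel_nm)
        row = dict(n_frames=k, threshold=thr, n_locs=len(table),
                   resolution_nm=res.resolution_nm, **{m: getattr(rep, m) for m in
                   ("pcc", "ssim", "ms_ssim", "mae", "psnr_db")})
        rows.append(row)
    return pd.DataFrame(rows)
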