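"""Low-density single-molecule localization and post-processing.

The chain mirrors the standard PAINT ground-truth reconstruction workflow:
net-gradient spot detection, maximum-likelihood fitting of a pixel-integrated
2-D Gaussian under Poisson noise, filtering on PSF width (sx, sy) and
localization precision (lpx, lpy), NeNA precision estimation, linking of
re-appearing emitters across dark gaps, redundant cross-correlation (RCC)
drift correction on localizations, and phase-correlation drift correction on
raw frames (used before network prediction).

Localization precision follows the Mortensen MLE formula with the EMCCD
excess-noise factor of 2 included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from scipy.special import erf
from skimage.registration import phase_cross_correlation

from .core import CameraModel, FrameStack, LocalizationTable

_SQRT2PI = np.sqrt(2.0 * np.pi)


# ---------------------------------------------------------------------------
# spot detection
# ---------------------------------------------------------------------------

def _net_gradient_kernels(box: int):
    h = box // 2
    ky = np.zeros((box, box))
    kx = np.zeros((box, box))
    for dy in range(-h, h + 1):
        for dx in range(-h, h + 1):
            if dx == 0 and dy == 0:
                continue
            r = np.hypot(dx, dy)
            # unit vector from the offset pixel toward the box center
            kx[h + dy, h + dx] = -dx / r
            ky[h + dy, h + dx] = -dy / r
    return ky, kx


def detect_spots(frame: np.ndarray, box_px: int = 7, min_net_gradient: float = 100.0):
    """Detect candidate single-molecule spots in one frame.

    Candidates are local maxima within a ``box_px`` window whose net gradient
    (sum of intensity gradients projected toward the candidate over the box)
    exceeds ``min_net_gradient``.  Candidates closer than box/2 to a border
    are discarded.  Returns (rows, cols) integer pixel indices.
    """
    if box_px < 5 or box_px % 2 == 0:
        raise ValueError("box_px must be odd and >= 5")
    frame = np.asarray(frame, dtype=np.float64)
    h = box_px // 2
    gy, gx = np.gradient(frame)
    ky, kx = _net_gradient_kernels(box_px)
    ng = ndimage.correlate(gx, kx, mode="constant") + ndimage.correlate(gy, ky, mode="constant")
    local_max = frame >= ndimage.maximum_filter(frame, size=box_px, mode="constant")
    cand = local_max & (ng > min_net_gradient)
    cand[:h, :] = cand[-h:, :] = False
    cand[:, :h] = cand[:, -h:] = False
    rows, cols = np.nonzero(cand)
    return rows, cols


# ---------------------------------------------------------------------------
# integrated-Gaussian MLE
# ---------------------------------------------------------------------------

def _model_and_jacobian(theta: np.ndarray, box: int):
    """Poisson means mu (n, box, box) and Jacobian (n, box*box, 6).

    theta columns: x0, y0, N, b, sx, sy (ROI corner-origin pixel units).
    """
    x0, y0, N, b, sx, sy = (theta[:, i][:, None] for i in range(6))
    edges = np.arange(box + 1)[None, :]
    tx = (edges - x0) / (np.sqrt(2.0) * sx)
    ty = (edges - y0) / (np.sqrt(2.0) * sy)
    ex = 0.5 * np.diff(erf(tx), axis=1)                      # (n, box)
    ey = 0.5 * np.diff(erf(ty), axis=1)
    gx = np.exp(-tx * tx)
    gy = np.exp(-ty * ty)
    dex_dx = -np.diff(gx, axis=1) / (_SQRT2PI * sx)
    dey_dy = -np.diff(gy, axis=1) / (_SQRT2PI * sy)
    dex_ds = -np.diff(tx * gx, axis=1) / (np.sqrt(np.pi) * sx)
    dey_ds = -np.diff(ty * gy, axis=1) / (np.sqrt(np.pi) * sy)

    n = theta.shape[0]
    mu = N[:, :, None] * ey[:, :, None] * ex[:, None, :] + b[:, :, None]
    J = np.empty((n, box * box, 6))
    outer = lambda a, c: (a[:, :, None] * c[:, None, :]).reshape(n, -1)
    J[:, :, 0] = N * outer(ey, dex_dx)
    J[:, :, 1] = N * outer(dey_dy, ex)
    J[:, :, 2] = outer(ey, ex)
    J[:, :, 3] = 1.0
    J[:, :, 4] = N * outer(ey, dex_ds)
    J[:, :, 5] = N * outer(dey_ds, ex)
    return mu, J


def _clamp(theta: np.ndarray, box: int) -> np.ndarray:
    theta[:, 0] = np.clip(theta[:, 0], 0.0, box)
    theta[:, 1] = np.clip(theta[:, 1], 0.0, box)
    theta[:, 2] = np.maximum(theta[:, 2], 1.0)
    theta[:, 3] = np.maximum(theta[:, 3], 1e-3)
    theta[:, 4] = np.clip(theta[:, 4], 0.3, box / 2.0)
    theta[:, 5] = np.clip(theta[:, 5], 0.3, box / 2.0)
    return theta


def _poisson_ll(data_flat: np.ndarray, mu: np.ndarray) -> np.ndarray:
    mu = np.maximum(mu.reshape(mu.shape[0], -1), 1e-9)
    return (data_flat * np.log(mu) - mu).sum(axis=1)


def fit_spots_mle(rois: np.ndarray, init_sigma_px: float = 1.2, max_iter: int = 40,
                  tol: float = 1e-6) -> pd.DataFrame:
    """Batched MLE of pixel-integrated Gaussian parameters on photon ROIs.

    ``rois`` is (n, box, box) in photon units.  Uses damped Fisher scoring of
    the Poisson likelihood; all ROIs are iterated together.  Returns a frame
    with columns x, y, photons, bg, sx, sy, lpx, lpy, valid — x/y in ROI
    corner-origin units.
    """
    rois = np.asarray(rois, dtype=np.float64)
    n, box, _ = rois.shape
    data = np.maximum(rois, 0.0)
    flat = data.reshape(n, -1)

    # moment initialization
    border = np.concatenate([data[:, 0, :], data[:, -1, :], data[:, :, 0], data[:, :, -1]], axis=1)
    b0 = np.maximum(np.median(border, axis=1), 1e-3)
    resid = np.maximum(data - b0[:, None, None], 0.0)
    mass = np.maximum(resid.sum(axis=(1, 2)), 1e-6)
    grid = np.arange(box) + 0.5
    x0 = (resid.sum(axis=1) * grid).sum(axis=1) / mass
    y0 = (resid.sum(axis=2) * grid).sum(axis=1) / mass
    theta = np.stack([x0, y0, np.maximum(mass, 10.0), b0,
                      np.full(n, init_sigma_px), np.full(n, init_sigma_px)], axis=1)
    theta = _clamp(theta, box)

    lam = np.full(n, 1e-3)
    mu, J = _model_and_jacobian(theta, box)
    ll = _poisson_ll(flat, mu)
    for _ in range(max_iter):
        mu_flat = np.maximum(mu.reshape(n, -1), 1e-9)
        r = flat / mu_flat - 1.0
        g = np.einsum("nk,nki->ni", r, J)
        H = np.einsum("nk,nki,nkj->nij", 1.0 / mu_flat, J, J)
        damp = lam[:, None] * np.maximum(np.einsum("nii->ni", H), 1e-12)
        Hd = H + damp[:, None] * np.eye(6)[None]
        try:
            delta = np.linalg.solve(Hd, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(Hd.reshape(-1, 6), g.reshape(-1, 1), rcond=None)[0]
        cand = _clamp(theta + delta, box)
        mu_c, J_c = _model_and_jacobian(cand, box)
        ll_c = _poisson_ll(flat, mu_c)
        accept = ll_c >= ll
        theta = np.where(accept[:, None], cand, theta)
        mu = np.where(accept[:, None, None], mu_c, mu)
        J = np.where(accept[:, None, None], J_c, J)
        ll = np.where(accept, ll_c, ll)
        lam = np.where(accept, lam * 0.5, lam * 8.0)
        if np.all(np.abs(delta[accept][:, :2]) < tol) and accept.all():
            break

    x, y, N, b, sx, sy = theta.T
    lpx = mortensen_precision(N, b, sx)
    lpy = mortensen_precision(N, b, sy)
    valid = ((x > 0.5) & (x < box - 0.5) & (y > 0.5) & (y < box - 0.5)
             & (N > 1.0) & np.isfinite(lpx) & np.isfinite(lpy))
    return pd.DataFrame(dict(x=x, y=y, photons=N, bg=b, sx=sx, sy=sy,
                             lpx=lpx, lpy=lpy, valid=valid))


def mortensen_precision(photons, bg, sigma_px, excess_noise: float = 2.0):
    """Mortensen MLE localization precision (px) for a pixelated Gaussian.

    ``excess_noise`` = 2 accounts for the EMCCD multiplication register.
    Pixel size a = 1 in pixel units; sigma_a^2 = sigma^2 + 1/12.
    """
    sa2 = np.asarray(sigma_px, dtype=float) ** 2 + 1.0 / 12.0
    N = np.maximum(np.asarray(photons, dtype=float), 1e-9)
    v = sa2 / N * (16.0 / 9.0 + 8.0 * np.pi * sa2 * np.asarray(bg, dtype=float) / N)
    return np.sqrt(excess_noise * v)


def fit_spot_mle(roi: np.ndarray, camera: CameraModel | None = None, **kw) -> pd.Series:
    """Fit a single ROI (ADU if ``camera`` given, else photons)."""
    roi = np.asarray(roi, dtype=np.float64)
    if camera is not None:
        roi = camera.adu_to_photons(roi)
    return fit_spots_mle(roi[None], **kw).iloc[0]


def localize(stack: FrameStack, box_px: int = 7, min_net_gradient: float = 400.0,
             init_sigma_px: float = 1.2, frames: slice | None = None) -> LocalizationTable:
    """Detect and MLE-fit single molecules in every frame of a stack."""
    photons = stack.photons(frames)
    h = box_px // 2
    rois, meta = [], []
    for f in range(photons.shape[0]):
        rows, cols = detect_spots(photons[f], box_px, min_net_gradient)
        for r, c in zip(rows, cols):
            rois.append(photons[f, r - h:r + h + 1, c - h:c + h + 1])
            meta.append((f, r - h, c - h))
    if not rois:
        return LocalizationTable.from_arrays(pixel_size_nm=stack.camera.pixel_size_nm,
                                             source="localize")
    fit = fit_spots_mle(np.stack(rois), init_sigma_px=init_sigma_px)
    meta = np.asarray(meta)
    fit["frame"] = meta[:, 0]
    fit["x"] = fit["x"] + meta[:, 2]
    fit["y"] = fit["y"] + meta[:, 1]
    fit = fit[fit.pop("valid")].reset_index(drop=True)
    table = LocalizationTable(df=fit[["frame", "x", "y", "photons", "sx", "sy",
                                      "bg", "lpx", "lpy"]].copy(),
                              pixel_size_nm=stack.camera.pixel_size_nm, source="localize")
    table.history.append(f"localize(box={box_px}, mng={min_net_gradient})")
    return table


# ---------------------------------------------------------------------------
# filtering / NeNA / linking
# ---------------------------------------------------------------------------

def filter_table(table: LocalizationTable, ranges: dict) -> LocalizationTable:
    """Keep rows whose columns fall inside the given closed intervals.

    ``ranges`` maps column name -> (lo, hi); e.g. sx/sy PSF-width windows and
    lpx/lpy precision caps.  Row order is preserved.
    """
    mask = np.ones(len(table), dtype=bool)
    for col, (lo, hi) in ranges.items():
        v = table.df[col].to_numpy()
        mask &= (v >= lo) & (v <= hi)
    out = table.df[mask].reset_index(drop=True)
    if len(out) == 0 and len(table):
        warnings.warn("filter_table removed all localizations")
    return table.copy_with(out, note=f"filter({ranges})")


DEFAULT_FILTER_RANGES = {"sx": (0.6, 2.0), "sy": (0.6, 2.0),
                         "lpx": (0.0, 0.3), "lpy": (0.0, 0.3)}


@dataclass
class PrecisionEstimate:
    """NeNA localization precision with its fitted distance distribution."""

    nena_px: float
    bin_centers: np.ndarray
    density: np.ndarray
    model_density: np.ndarray
    params: dict

    def __post_init__(self):
        if not self.nena_px > 0:
            raise ValueError("nena_px must be > 0")


def _nena_model(d, sigma, a, c):
    corr = a * (d / (2.0 * sigma ** 2)) * np.exp(-d * d / (4.0 * sigma ** 2))
    return corr + c * d


def estimate_nena(table: LocalizationTable, max_d_px: float = 2.0,
                  bins: int = 100) -> PrecisionEstimate:
    """Nearest-neighbor-based analysis (NeNA) of localization precision.

    Distances between each localization and its nearest neighbor in the next
    frame are histogrammed and fitted with the 2-D correlated-pair
    distribution plus a linear (uniform-background) term; the returned sigma
    is the experimental localization precision in pixels.
    """
    df = table.df
    frames = df["frame"].to_numpy()
    if len(np.unique(frames)) < 2:
        raise ValueError("need localizations in at least 2 frames")
    xy = df[["x", "y"]].to_numpy()
    dists = []
    order = np.argsort(frames, kind="stable")
    frames_s, xy_s = frames[order], xy[order]
    uniq, starts = np.unique(frames_s, return_index=True)
    starts = np.append(starts, len(frames_s))
    by_frame = {f: xy_s[s:e] for f, s, e in zip(uniq, starts[:-1], starts[1:])}
    for f in uniq[:-1]:
        nxt = by_frame.get(f + 1)
        if nxt is None or len(nxt) == 0:
            continue
        d, _ = cKDTree(nxt).query(by_frame[f], k=1)
        dists.append(d[d <= max_d_px])
    if not dists:
        raise ValueError("no consecutive-frame neighbor pairs found")
    d = np.concatenate(dists)
    if len(d) < 30:
        raise ValueError(f"too few neighbor pairs for NeNA ({len(d)})")
    hist, edges = np.histogram(d, bins=bins, range=(0, max_d_px))
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    density = hist / (len(d) * width)
    sigma0 = max(centers[np.argmax(hist)] / np.sqrt(2.0), 0.02)
    p0 = [sigma0, 1.0, 1e-3]
    popt, _ = curve_fit(_nena_model, centers, density, p0=p0,
                        bounds=([1e-3, 0.0, 0.0], [max_d_px, 10.0, 10.0]),
                        maxfev=20000)
    return PrecisionEstimate(nena_px=float(popt[0]), bin_centers=centers, density=density,
                             model_density=_nena_model(centers, *popt),
                             params=dict(sigma=popt[0], amplitude=popt[1], background=popt[2]))


def link_localizations(table: LocalizationTable, radius_px: float | None = None,
                       max_dark_frames: int = 5) -> LocalizationTable:
    """Merge localizations of one emitter re-appearing across frames.

    Chains are built transitively: a localization joins an open chain if it
    lies within ``radius_px`` of the chain's last position and the dark gap
    (frames with the emitter off between sightings) does not exceed
    ``max_dark_frames``.  The default radius is four times the NeNA precision.
    Each chain merges to one row: photon-weighted mean position, summed
    photons, first frame, combined precision.
    """
    if radius_px is None:
        radius_px = 4.0 * estimate_nena(table).nena_px
    if radius_px <= 0:
        raise ValueError("radius_px must be > 0")
    df = table.df.sort_values("frame", kind="stable").reset_index(drop=True)
    n = len(df)
    link_id = np.full(n, -1, dtype=np.int64)
    frames = df["frame"].to_numpy()
    xy = df[["x", "y"]].to_numpy()

    open_ids: list[int] = []      # chain indices
    open_pos: list = []           # last positions
    open_frame: list = []         # last frames
    next_chain = 0
    for f in np.unique(frames):
        keep = [i for i in range(len(open_ids)) if f - open_frame[i] - 1 <= max_dark_frames]
        open_ids = [open_ids[i] for i in keep]
        open_pos = [open_pos[i] for i in keep]
        open_frame = [open_frame[i] for i in keep]
        idx = np.nonzero(frames == f)[0]
        claimed = set()
        if open_ids:
            tree = cKDTree(np.asarray(open_pos))
            dists, nbr = tree.query(xy[idx], k=1)
            for rank in np.argsort(dists):
                i, dist, j = idx[rank], dists[rank], int(nbr[rank])
                if dist <= radius_px and j not in claimed:
                    link_id[i] = open_ids[j]
                    open_pos[j] = xy[i]
                    open_frame[j] = f
                    claimed.add(j)
        for i in idx:
            if link_id[i] < 0:
                link_id[i] = next_chain
                open_ids.append(next_chain)
                open_pos.append(xy[i])
                open_frame.append(f)
                next_chain += 1

    df = df.assign(link_id=link_id)
    w = df["photons"].to_numpy()
    g = df.groupby("link_id", sort=True)
    wsum = g["photons"].sum()
    merged = pd.DataFrame({
        "frame": g["frame"].min(),
        "x": g.apply(lambda s: np.average(s["x"], weights=s["photons"]), include_groups=False),
        "y": g.apply(lambda s: np.average(s["y"], weights=s["photons"]), include_groups=False),
        "photons": wsum,
        "sx": g.apply(lambda s: np.average(s["sx"], weights=s["photons"]), include_groups=False),
        "sy": g.apply(lambda s: np.average(s["sy"], weights=s["photons"]), include_groups=False),
        "bg": g["bg"].mean(),
        "lpx": g["lpx"].apply(lambda s: 1.0 / np.sqrt((1.0 / s ** 2).sum())),
        "lpy": g["lpy"].apply(lambda s: 1.0 / np.sqrt((1.0 / s ** 2).sum())),
        "n_events": g.size(),
    }).reset_index()
    return table.copy_with(merged, note=f"link(r={radius_px:.3f}, dark<={max_dark_frames})")


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

@dataclass
class DriftTrajectory:
    """Per-frame lateral drift (dx, dy) in camera pixels; frame 0 is zero."""

    dxy: np.ndarray  # (n_frames, 2)
    method: str
    segment_frames: int | None = None


def render_locs(table: LocalizationTable, oversampling: int = 1, blur_sigma_px: float = 0.0,
                shape: tuple | None = None, frame_range: tuple | None = None) -> np.ndarray:
    """Render localizations to a 2-D histogram image.

    ``oversampling`` divides the camera pixel: the rendered pixel size is
    pixel_size_nm / oversampling.  ``blur_sigma_px`` is a Gaussian blur in
    rendered pixels.  Histogram sum equals the rendered row count (blur
    preserves it up to boundary loss).
    """
    if oversampling < 1:
        raise ValueError("oversampling must be >= 1")
    df = table.df
    if frame_range is not None:
        f = df["frame"].to_numpy()
        df = df[(f >= frame_range[0]) & (f < frame_range[1])]
    if shape is None:
        if len(df) == 0:
            return np.zeros((oversampling, oversampling))
        shape = (int(np.ceil(df["y"].max())) + 1, int(np.ceil(df["x"].max())) + 1)
    H, W = shape
    img, _, _ = np.histogram2d(df["y"].to_numpy(), df["x"].to_numpy(),
                               bins=[H * oversampling, W * oversampling],
                               range=[[0, H], [0, W]])
    if blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, blur_sigma_px)
    return img


def rcc_drift_correct(table: LocalizationTable, segment_frames: int = 200,
                      oversampling: int = 4, shape: tuple | None = None,
                      blur_sigma_px: float = 1.0):
    """Redundant cross-correlation drift correction on a localization table.

    The stack is split into temporal segments, each segment is rendered to a
    super-resolved sub-image, shifts between *all* segment pairs are measured
    by upsampled phase correlation, and the over-determined pairwise system is
    solved by least squares for the per-segment drift, which is interpolated
    to every frame and subtracted from the coordinates.
    """
    frames = table.df["frame"].to_numpy()
    n_frames = int(frames.max()) + 1
    if n_frames < 2 * segment_frames:
        raise ValueError("need at least two segments: n_frames >= 2 * segment_frames")
    n_seg = n_frames // segment_frames
    bounds = [(s * segment_frames,
               (s + 1) * segment_frames if s < n_seg - 1 else n_frames)
              for s in range(n_seg)]
    if shape is None:
        shape = (int(np.ceil(table.df["y"].max())) + 1, int(np.ceil(table.df["x"].max())) + 1)
    imgs = [render_locs(table, oversampling, blur_sigma_px, shape, frame_range=b)
            for b in bounds]

    rows, rhs_x, rhs_y = [], [], []
    for i in range(n_seg):
        for j in range(i + 1, n_seg):
            if imgs[i].sum() == 0 or imgs[j].sum() == 0:
                continue
            shift, _, _ = phase_cross_correlation(imgs[i], imgs[j], upsample_factor=50,
                                                  normalization=None)
            # returned shift registers segment j onto i: (drift_i - drift_j);
            # the pairwise unknown d_j - d_i is its negative
            row = np.zeros(n_seg)
            row[j], row[i] = 1.0, -1.0
            rows.append(row)
            rhs_y.append(-shift[0] / oversampling)
            rhs_x.append(-shift[1] / oversampling)
    if not rows:
        raise ValueError("no valid segment pairs for RCC")
    A = np.asarray(rows)
    dx_seg = np.linalg.lstsq(A, np.asarray(rhs_x), rcond=None)[0]
    dy_seg = np.linalg.lstsq(A, np.asarray(rhs_y), rcond=None)[0]

    centers = np.array([(b[0] + b[1]) / 2.0 for b in bounds])
    t = np.arange(n_frames)
    dx = np.interp(t, centers, dx_seg)
    dy = np.interp(t, centers, dy_seg)
    dx -= dx[0]
    dy -= dy[0]
    traj = np.stack([dx, dy], axis=1)

    df = table.df.copy()
    f = df["frame"].to_numpy()
    df["x"] = df["x"].to_numpy() - traj[f, 0]
    df["y"] = df["y"].to_numpy() - traj[f, 1]
    out = table.copy_with(df, note=f"rcc(segment={segment_frames})")
    return out, DriftTrajectory(dxy=traj, method="rcc", segment_frames=segment_frames)


def frame_xcorr_drift(stack: FrameStack, reference: str = "first", upsample_factor: int = 20):
    """Per-frame drift correction of raw frames by phase cross-correlation.

    Estimates the subpixel shift of each frame against a reference (the first
    frame or the stack mean), then resamples each frame back by interpolation.
    This is the raw-frame correction applied to high-density data before
    network prediction.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    data = stack.frames.astype(np.float64)
    ref = data[0] if reference == "first" else data.mean(axis=0)
    if ref.std() == 0:
        warnings.warn("featureless reference frame; assuming zero drift")
        traj = np.zeros((stack.n_frames, 2))
        return stack, DriftTrajectory(dxy=traj, method="frame_xcorr")
    traj = np.zeros((stack.n_frames, 2))
    out = np.empty_like(stack.frames)
    for i in range(stack.n_frames):
        if data[i].std() == 0:
            warnings.warn(f"featureless frame {i}; zero shift assumed")
            shift = np.zeros(2)
        else:
            shift, _, _ = phase_cross_correlation(ref - ref.mean(), data[i] - data[i].mean(),
                                                  upsample_factor=upsample_factor,
                                                  normalization=None)
        # shift (y, x) moves frame i onto the reference
        traj[i] = (-shift[1], -shift[0])
        corrected = ndimage.shift(data[i], (shift[0], shift[1]), order=1, mode="nearest")
        out[i] = np.clip(np.round(corrected), 0, 65535).astype(np.uint16)
    traj -= traj[0]
    locs = None
    if stack.true_locs is not None:
        df = stack.true_locs.df.copy()
        f = df["frame"].to_numpy()
        df["x"] = df["x"].to_numpy() - traj[f, 0]
        df["y"] = df["y"].to_numpy() - traj[f, 1]
        locs = stack.true_locs.copy_with(df, note="frame_xcorr_drift")
    return (FrameStack(frames=out, camera=stack.camera, true_locs=locs),
            DriftTrajectory(dxy=traj, method="frame_xcorr"))
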