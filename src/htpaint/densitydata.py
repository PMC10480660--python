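"""High-density training patches from summed low-density acquisitions.

Low-density PAINT frames carry sparse, well-separated emitters whose positions
are known from single-molecule fitting.  Summing k randomly chosen low-density
patches pixel-wise yields a high-density patch whose emitter list is the exact
concatenation of the k source lists — overlapping PSFs with perfectly known
coordinates, which is what the density-map network trains on.  Summing k
patches multiplies the mean emitter density by exactly k (e.g. 12 x 0.109 ~
1.3 emitters/um^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FrameStack, LocalizationTable, substream


@dataclass
class TrainingPatchSet:
    """Paired patch images (photon units) and exact emitter coordinate lists.

    ``patches`` is (n, P, P); ``labels[i]`` is an (m_i, 2) array of (x, y)
    emitter positions in patch pixel coordinates (corner origin); ``meta``
    records densities, patch size, summing multiplicity and seed.
    """

    patches: np.ndarray
    labels: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.patches = np.asarray(self.patches, dtype=np.float32)
        if self.patches.ndim != 3 or self.patches.shape[1] != self.patches.shape[2]:
            raise ValueError("patches must be (n, P, P)")
        if len(self.labels) != len(self.patches):
            raise ValueError("one label list per patch required")
        P = self.patch_px
        for lab in self.labels:
            lab = np.asarray(lab)
            if len(lab) and (lab.min() < 0 or lab.max() >= P):
                raise ValueError("label coordinates must lie in [0, patch_px)")

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def patch_px(self) -> int:
        return int(self.patches.shape[1])

    def mean_label_count(self) -> float:
        return float(np.mean([len(l) for l in self.labels]))

    def mean_density_per_um2(self) -> float:
        """Mean emitters per um^2 per patch, from labels and pixel size."""
        px_um = self.meta.get("pixel_size_nm", 157.0) / 1e3
        area = (self.patch_px * px_um) ** 2
        return self.mean_label_count() / area


def extract_patches(stack: FrameStack, table: LocalizationTable, patch_px: int = 17,
                    n: int = 10000, seed: int = 0) -> TrainingPatchSet:
    """Cut n random low-density patches (photon units) with their emitters.

    Patches are sampled uniformly over (frame, x-corner, y-corner); each patch
    carries the localization rows whose positions fall inside it, re-expressed
    in patch coordinates.
    """
    n_frames, H, W = stack.shape
    if patch_px > min(H, W):
        raise ValueError("patch_px exceeds frame size")
    rng = substream(seed, "extract_patches")
    photons = stack.photons()
    frames_sel = rng.integers(0, n_frames, size=n)
    cys = rng.integers(0, H - patch_px + 1, size=n)
    cxs = rng.integers(0, W - patch_px + 1, size=n)

    df = table.df
    tf = df["frame"].to_numpy()
    tx = df["x"].to_numpy()
    ty = df["y"].to_numpy()
    order = np.argsort(tf, kind="stable")
    tf, tx, ty = tf[order], tx[order], ty[order]
    starts = np.searchsorted(tf, np.arange(n_frames + 1))

    patches = np.empty((n, patch_px, patch_px), dtype=np.float32)
    labels = []
    for i, (f, cy, cx) in enumerate(zip(frames_sel, cys, cxs)):
        patches[i] = photons[f, cy:cy + patch_px, cx:cx + patch_px]
        s, e = starts[f], starts[f + 1]
        x, y = tx[s:e], ty[s:e]
        inside = (x >= cx) & (x < cx + patch_px) & (y >= cy) & (y < cy + patch_px)
        labels.append(np.stack([x[inside] - cx, y[inside] - cy], axis=1)
                      if inside.any() else np.empty((0, 2)))
    px_um2 = (patch_px * stack.camera.pixel_size_nm / 1e3) ** 2
    meta = dict(source_density=float(np.mean([len(l) for l in labels]) / px_um2),
                patch_px=patch_px, pixel_size_nm=stack.camera.pixel_size_nm,
                n_summed_per_patch=1, seed=int(seed))
    return TrainingPatchSet(patches=patches, labels=labels, meta=meta)


def sum_patches(low_patches: TrainingPatchSet, k_per_sum: int = 12, n_out: int = 30000,
                seed: int = 0) -> TrainingPatchSet:
    """Sum k randomly selected low-density patches into each training patch.

    Selection is with replacement.  Pixel values add exactly and the label
    list of an output patch is the concatenation of its k source lists, so
    emitter count and photons are conserved by construction.
    """
    if k_per_sum < 1:
        raise ValueError("k_per_sum must be >= 1")
    rng = substream(seed, "sum_patches")
    P = low_patches.patch_px
    idx = rng.integers(0, len(low_patches), size=(n_out, k_per_sum))
    patches = low_patches.patches[idx].sum(axis=1)
    labels = [np.concatenate([low_patches.labels[j] for j in row])
              if any(len(low_patches.labels[j]) for j in row) else np.empty((0, 2))
              for row in idx]
    meta = dict(low_patches.meta)
    meta.update(n_summed_per_patch=k_per_sum * meta.get("n_summed_per_patch", 1),
                target_density=meta.get("source_density", np.nan) * k_per_sum,
                seed=int(seed))
    return TrainingPatchSet(patches=patches, labels=labels, meta=meta)


def background_stats(images: np.ndarray) -> tuple:
    """(median, MAD) of pixel values — a robust background descriptor for
    sparse single-molecule data, where most pixels are background."""
    med = float(np.median(images))
    mad = float(np.median(np.abs(images - med)))
    return med, mad


def adjust_background(patch_set: TrainingPatchSet, target_bg_stats: tuple,
                      rescale_noise: bool = False) -> TrainingPatchSet:
    """Shift patch backgrounds to match a reference (median, MAD).

    An additive offset aligns the median; optionally the spread around the
    median is rescaled to match the reference MAD.  Labels are unchanged.
    """
    t_med, t_mad = float(target_bg_stats[0]), float(target_bg_stats[1])
    if not (np.isfinite(t_med) and np.isfinite(t_mad)):
        raise ValueError("target background stats must be finite")
    cur_med, cur_mad = background_stats(patch_set.patches)
    patches = patch_set.patches.astype(np.float64)
    if rescale_noise and cur_mad > 0:
        patches = (patches - cur_med) * (t_mad / cur_mad) + t_med
    else:
        patches = patches + (t_med - cur_med)
    meta = dict(patch_set.meta)
    meta["background_adjusted_to"] = (t_med, t_mad)
    return TrainingPatchSet(patches=patches.astype(np.float32),
                            labels=patch_set.labels, meta=meta)


def make_label_maps(patch_set: TrainingPatchSet, upsampling: int,
                    amplitude: float = 1.0) -> np.ndarray:
    """Upsampled spike maps: unit mass at each emitter's nearest fine pixel.

    Returns (n, P*u, P*u); coincident emitters accumulate, so each map sums to
    ``amplitude`` times its label count.
    """
    if upsampling < 1:
        raise ValueError("upsampling must be a positive integer")
    P, u = patch_set.patch_px, int(upsampling)
    maps = np.zeros((len(patch_set), P * u, P * u), dtype=np.float32)
    for i, lab in enumerate(patch_set.labels):
        if len(lab) == 0:
            continue
        lab = np.asarray(lab)
        if lab.min() < 0 or lab.max() >= P:
            raise ValueError("label outside patch bounds")
        cols = np.clip((lab[:, 0] * u).astype(np.int64), 0, P * u - 1)
        rows = np.clip((lab[:, 1] * u).astype(np.int64), 0, P * u - 1)
        np.add.at(maps[i], (rows, cols), amplitude)
    return maps


def center_crop(patch_set: TrainingPatchSet, crop_px: int = 16) -> TrainingPatchSet:
    """Center-crop patches (e.g. 17 -> 16 px before training), shifting labels
    and dropping emitters that fall outside the crop."""
    P = patch_set.patch_px
    if crop_px > P:
        raise ValueError("crop_px larger than patch")
    start = (P - crop_px) // 2
    patches = patch_set.patches[:, start:start + crop_px, start:start + crop_px]
    labels = []
    for lab in patch_set.labels:
        lab = np.asarray(lab)
        if len(lab) == 0:
            labels.append(np.empty((0, 2)))
            continue
        shifted = lab - start
        ok = (shifted >= 0).all(axis=1) & (shifted < crop_px).all(axis=1)
        labels.append(shifted[ok])
    meta = dict(patch_set.meta)
    meta["patch_px"] = crop_px
    return TrainingPatchSet(patches=patches.copy(), labels=labels, meta=meta)
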