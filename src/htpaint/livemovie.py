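"""Sliding-window super-resolution movies of live-cell dynamics.

High-density live-cell acquisitions are reconstructed as a movie: a temporal
window (default 400 frames) slides in steps of 20 frames over the extracted
localization stream; each window is rendered on the upsampled grid, contrast
is saturated at the 99th percentile and normalized per frame to [0, 1], a
mean filter suppresses isolated background localizations, a 1.5 px Gaussian
smooths the structure, and the styled frames are stitched into a video.  At
50 ms integration a 20-frame step gives 1 s between movie frames.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .core import LocalizationTable
from .locfit import render_locs


@dataclass
class MovieConfig:
    """Windowing and styling parameters for live-cell movie generation."""

    window_frames: int = 400
    step_frames: int = 20
    saturation_percentile: float = 99.0
    mean_filter_px: int = 3
    gauss_sigma_px: float = 1.5
    fps: float = 30.0
    oversampling: int = 8
    integration_time_ms: float = 50.0
    output_size_px: tuple | None = None

    def __post_init__(self):
        if not 1 <= self.step_frames <= self.window_frames:
            raise ValueError("need 1 <= step_frames <= window_frames")
        if not 0 < self.saturation_percentile <= 100:
            raise ValueError("saturation_percentile must be in (0, 100]")


def plan_windows(n_frames: int, window: int = 400, step: int = 20) -> list:
    """Sliding-window plan: [(start, end), ...) with end exclusive.

    Windows are [i*step, i*step + window) for i = 0 .. floor((n - w)/s); a
    stack shorter than one window yields a single truncated window with a
    warning.
    """
    if n_frames < window:
        warnings.warn(f"stack shorter than one window ({n_frames} < {window}); "
                      "emitting a single truncated window")
        return [(0, n_frames)]
    count = (n_frames - window) // step + 1
    return [(i * step, i * step + window) for i in range(count)]


def window_image(table: LocalizationTable, window: tuple, shape: tuple,
                 oversampling: int = 8) -> np.ndarray:
    """Render the localizations of one temporal window on the upsampled grid."""
    return render_locs(table, oversampling=oversampling, shape=shape,
                       frame_range=window)


def style_frame(image: np.ndarray, config: MovieConfig | None = None) -> np.ndarray:
    """Contrast/style one rendered window for display.

    Clip at the per-frame saturation percentile, normalize to [0, 1], mean
    filter, then Gaussian smoothing.  An all-zero frame passes through as-is
    (kept for temporal continuity).
    """
    from scipy import ndimage

    cfg = config or MovieConfig()
    img = np.asarray(image, dtype=np.float64)
    if np.any(img < 0):
        raise ValueError("window image must be nonnegative")
    clip = np.percentile(img, cfg.saturation_percentile)
    if clip <= 0:
        clip = img.max()
    if clip <= 0:
        return np.zeros_like(img)
    img = np.minimum(img, clip) / clip
    if cfg.mean_filter_px > 1:
        img = ndimage.uniform_filter(img, size=cfg.mean_filter_px)
    if cfg.gauss_sigma_px > 0:
        img = ndimage.gaussian_filter(img, cfg.gauss_sigma_px)
    return np.clip(img, 0.0, 1.0)


def make_movie_frames(table: LocalizationTable, n_frames: int, shape: tuple,
                      config: MovieConfig | None = None):
    """Windowed, styled movie frames plus their timestamps in seconds.

    The timestamp of movie frame i is the start of its window,
    i * step * integration time.
    """
    cfg = config or MovieConfig()
    windows = plan_windows(n_frames, cfg.window_frames, cfg.step_frames)
    frames = [style_frame(window_image(table, w, shape, cfg.oversampling), cfg)
              for w in windows]
    t = np.array([w[0] * cfg.integration_time_ms / 1e3 for w in windows])
    return frames, t, windows


def stitch_movie(frames: list, out_path, config: MovieConfig | None = None,
                 timestamps=None):
    """Encode styled frames to a video file, or fall back to a PNG sequence.

    Frames (floats in [0, 1]) are quantized to 8-bit.  If an MP4 encoder is
    unavailable the frames are written as numbered PNGs in a directory named
    after the output.  A JSON sidecar records the window plan timing.
    Returns a manifest dict with the written paths.
    """
    cfg = config or MovieConfig()
    if len(frames) == 0:
        raise ValueError("no frames to stitch")
    out_path = Path(out_path)
    arrs = [np.round(np.clip(f, 0, 1) * 255).astype(np.uint8) for f in frames]
    if timestamps is None:
        timestamps = [i * cfg.step_frames * cfg.integration_time_ms / 1e3
                      for i in range(len(arrs))]
    manifest = dict(n_frames=len(arrs), fps=cfg.fps,
                    duration_s=len(arrs) / cfg.fps,
                    frame_shape=list(arrs[0].shape),
                    timestamps_s=[float(t) for t in timestamps],
                    config=asdict(cfg))
    written = None
    if out_path.suffix.lower() == ".mp4":
        try:
            import imageio.v2 as iio
            with iio.get_writer(out_path, fps=cfg.fps) as w:
                for a in arrs:
                    w.append_data(a)
            written = str(out_path)
        except Exception as exc:  # encoder missing -> image sequence
            warnings.warn(f"mp4 encoder unavailable ({exc}); writing PNG sequence")
    if written is None:
        import imageio.v2 as iio
        seq_dir = out_path.with_suffix("") if out_path.suffix else out_path
        seq_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, a in enumerate(arrs):
            p = seq_dir / f"frame_{i:05d}.png"
            iio.imwrite(p, a)
            paths.append(str(p))
        written = str(seq_dir)
        manifest["frame_files"] = paths
    manifest["output"] = written
    sidecar = Path(str(out_path) + ".json")
    sidecar.write_text(json.dumps(manifest, indent=2))
    manifest["sidecar"] = str(sidecar)
    return manifest
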