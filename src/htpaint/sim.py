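"""Synthetic PAINT acquisitions with exchangeable-label kinetics.

Emulates HT-PAINT imaging of fluorescently tagged cellular structures: binding
sites are distributed along a synthetic structure (filaments, tubules or a
network), transient probe binding produces a stationary stream of active
emitters (no photobleaching — exchangeable ligands replenish the signal), and
an EMCCD forward model turns expected photon images into 16-bit camera frames.

The binding process is an M/G/infinity queue: event starts are Poisson in
time, on-durations are geometric (discrete memoryless dwell), so the expected
number of active emitters per frame is constant over the whole acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .core import CameraModel, FrameStack, LocalizationTable, substream


@dataclass(frozen=True)
class StructureModel:
    """Point set of candidate binding sites inside a rectangular field.

    ``points`` are (x, y) in nanometers; ``field_size_um`` is the square field
    side length in micrometers.
    """

    kind: str
    points: np.ndarray  # (n, 2) nm
    field_size_um: float
    seed: int

    @property
    def area_um2(self) -> float:
        return self.field_size_um ** 2


@dataclass
class BindingEvents:
    """Transient binding events: each row is one probe-binding episode."""

    x_nm: np.ndarray
    y_nm: np.ndarray
    start_frame: np.ndarray  # inclusive
    end_frame: np.ndarray    # inclusive
    photon_rate: np.ndarray  # photons / frame while bound
    n_frames: int
    field_size_um: float
    mean_density: float      # emitters / um^2 / frame (expected active)

    def __len__(self) -> int:
        return len(self.x_nm)

    def active_counts(self) -> np.ndarray:
        """Number of active emitters in each frame (direct tally)."""
        counts = np.zeros(self.n_frames, dtype=np.int64)
        np.add.at(counts, self.start_frame, 1)
        ends = self.end_frame + 1
        inside = ends < self.n_frames
        np.add.at(counts, ends[inside], -1)
        return np.cumsum(counts)


def _wander_curve(rng, field_nm, length_nm, step_nm=50.0, curvature=0.15):
    """Random smooth curve inside the field, returned as dense vertices."""
    n_steps = max(2, int(np.ceil(length_nm / step_nm)))
    pos = rng.uniform(0.0, field_nm, size=2)
    theta = rng.uniform(0, 2 * np.pi)
    pts = np.empty((n_steps + 1, 2))
    pts[0] = pos
    for i in range(n_steps):
        theta += rng.normal(0, curvature)
        step = step_nm * np.array([np.cos(theta), np.sin(theta)])
        nxt = pts[i] + step
        # reflect off field borders to stay inside
        for ax in range(2):
            if nxt[ax] < 0:
                nxt[ax] = -nxt[ax]
                theta = np.pi - theta if ax == 0 else -theta
            elif nxt[ax] > field_nm:
                nxt[ax] = 2 * field_nm - nxt[ax]
                theta = np.pi - theta if ax == 0 else -theta
        pts[i + 1] = nxt
    return pts


def _sites_along(vertices: np.ndarray, spacing_nm: float) -> np.ndarray:
    """Binding sites at fixed arc-length spacing along a polyline.

    Sites sit at arc lengths (k + 1/2) * spacing, so an exact subdivision of a
    curve of length L yields exactly L / spacing sites.
    """
    seg = np.diff(vertices, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n_sites = int(np.floor(total / spacing_nm + 1e-9))
    if n_sites == 0:
        return np.empty((0, 2))
    s = (np.arange(n_sites) + 0.5) * spacing_nm
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
    frac = (s - cum[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
    return vertices[idx] + seg[idx] * frac[:, None]


def generate_structure(kind: str, field_size_um: float, structure_params: dict | None = None,
                       seed: int = 0) -> StructureModel:
    """Generate a synthetic labeled structure (binding-site point set).

    kind: ``filaments`` (smooth curves, vimentin-like), ``tubules`` (curves
    with a hollow-tube cross-section, mitochondria-like) or ``network``
    (random planar graph, ER-like).  ``structure_params`` keys:
    ``n_filaments``/``n_tubules``/``n_nodes``, ``length_um`` (per curve),
    ``site_spacing_nm``, ``tubule_radius_nm``.
    """
    if field_size_um <= 0:
        raise ValueError("field_size_um must be > 0")
    p = dict(structure_params or {})
    rng = substream(seed, f"structure:{kind}")
    field_nm = field_size_um * 1e3
    spacing = float(p.get("site_spacing_nm", 10.0))

    if kind == "filaments":
        n_fil = int(p.get("n_filaments", 8))
        length_nm = float(p.get("length_um", 0.8 * field_size_um)) * 1e3
        pts = [_sites_along(_wander_curve(rng, field_nm, length_nm), spacing)
               for _ in range(n_fil)]
        points = np.concatenate(pts) if pts else np.empty((0, 2))
    elif kind == "tubules":
        n_tub = int(p.get("n_tubules", 6))
        length_nm = float(p.get("length_um", 0.5 * field_size_um)) * 1e3
        radius = float(p.get("tubule_radius_nm", 150.0))
        pts = []
        for _ in range(n_tub):
            center = _sites_along(_wander_curve(rng, field_nm, length_nm, curvature=0.25), spacing)
            if len(center) == 0:
                continue
            phi = rng.uniform(0, 2 * np.pi, size=len(center))
            pts.append(center + radius * np.stack([np.cos(phi), np.sin(phi)], axis=1))
        points = np.concatenate(pts) if pts else np.empty((0, 2))
    elif kind == "network":
        n_nodes = int(p.get("n_nodes", 20))
        nodes = rng.uniform(0.1 * field_nm, 0.9 * field_nm, size=(n_nodes, 2))
        pts = []
        # sparse connectivity: each node links to its 2 nearest neighbors
        if n_nodes >= 2:
            d2 = ((nodes[:, None, :] - nodes[None, :, :]) ** 2).sum(-1)
            np.fill_diagonal(d2, np.inf)
            for i in range(n_nodes):
                for j in np.argsort(d2[i])[:2]:
                    if i < j:
                        pts.append(_sites_along(nodes[[i, j]], spacing))
        points = np.concatenate(pts) if pts else np.empty((0, 2))
    else:
        raise ValueError(f"unknown structure kind: {kind!r}")

    points = points[((points >= 0) & (points <= field_nm)).all(axis=1)]
    return StructureModel(kind=kind, points=points, field_size_um=field_size_um, seed=seed)


def sample_binding_events(structure: StructureModel, mean_density: float, n_frames: int,
                          mean_on_frames: float = 3.0, photon_rate: float = 2000.0,
                          seed: int = 0) -> BindingEvents:
    """Sample stationary transient-binding events on a structure.

    ``mean_density`` is the expected number of simultaneously active emitters
    per um^2 in every frame (the process has no decay term: exchangeable
    labels re-bind indefinitely).  On-durations are geometric with mean
    ``mean_on_frames``; binding sites are drawn from the structure point set
    with replacement (several events may revisit one tag).
    """
    if mean_density < 0:
        raise ValueError("mean_density must be >= 0")
    if n_frames < 1 or mean_on_frames < 1:
        raise ValueError("n_frames and mean_on_frames must be >= 1")
    rng = substream(seed, "binding")
    target_active = mean_density * structure.area_um2
    if target_active > 0 and len(structure.points) == 0:
        raise ValueError("structure has no binding sites but mean_density > 0")
    if target_active == 0:
        empty = np.empty(0)
        return BindingEvents(empty, empty, empty.astype(int), empty.astype(int), empty,
                             n_frames, structure.field_size_um, mean_density)

    p_off = 1.0 / mean_on_frames
    # stationarity: initial actives ~ Poisson(target); geometric dwell is
    # memoryless so residual durations are again geometric
    starts = [np.zeros(rng.poisson(target_active), dtype=np.int64)]
    # new events per frame ~ Poisson(target / mean_on)
    rate_new = target_active * p_off
    counts = rng.poisson(rate_new, size=n_frames)
    for f in np.nonzero(counts)[0]:
        starts.append(np.full(counts[f], f, dtype=np.int64))
    start = np.concatenate(starts)
    dur = rng.geometric(p_off, size=len(start))  # >= 1 frame
    end = np.minimum(start + dur - 1, n_frames - 1)
    site_idx = rng.integers(0, len(structure.points), size=len(start))
    xy = structure.points[site_idx]
    rate = np.full(len(start), float(photon_rate))
    order = np.argsort(start, kind="stable")
    return BindingEvents(xy[order, 0], xy[order, 1], start[order], end[order], rate[order],
                         n_frames, structure.field_size_um, mean_density)


def _integrated_gaussian_patches(xc, yc, photons, sigma_px, half):
    """Pixel-integrated 2-D Gaussian patches around each emitter.

    Returns (corner_rows, corner_cols, patches) where patches has shape
    (n, w, w), w = 2*half + 1, and xc/yc are in corner-origin pixel units.
    """
    w = 2 * half + 1
    cc = np.floor(xc).astype(np.int64) - half
    cr = np.floor(yc).astype(np.int64) - half
    s2 = np.sqrt(2.0) * sigma_px
    ex_edges = cc[:, None] + np.arange(w + 1)[None, :]
    ey_edges = cr[:, None] + np.arange(w + 1)[None, :]
    ex = 0.5 * np.diff(erf((ex_edges - xc[:, None]) / s2), axis=1)
    ey = 0.5 * np.diff(erf((ey_edges - yc[:, None]) / s2), axis=1)
    patches = photons[:, None, None] * ey[:, :, None] * ex[:, None, :]
    return cr, cc, patches


def expected_photon_frames(events: BindingEvents, psf_sigma_px: float, camera: CameraModel,
                           bg_photons: float = 0.0, frame_shape: tuple | None = None):
    """Expected photon image per frame (noise-free forward model).

    Each active emitter contributes a pixel-integrated Gaussian with expected
    total photons = photon_rate (full frames on).  Emitters near borders
    contribute truncated PSFs.
    """
    px_nm = camera.pixel_size_nm
    if frame_shape is None:
        side = int(round(events.field_size_um * 1e3 / px_nm))
        frame_shape = (side, side)
    H, W = frame_shape
    if np.any(events.photon_rate < 0):
        raise ValueError("negative photon rate")
    images = np.full((events.n_frames, H, W), float(bg_photons))
    if len(events) == 0:
        return images, frame_shape
    # expand events into per-frame instances
    dur = (events.end_frame - events.start_frame + 1).astype(np.int64)
    inst_frame = np.repeat(events.start_frame, dur) + _ragged_arange(dur)
    inst_x = np.repeat(events.x_nm / px_nm, dur)
    inst_y = np.repeat(events.y_nm / px_nm, dur)
    inst_rate = np.repeat(events.photon_rate, dur)
    half = max(3, int(np.ceil(4 * psf_sigma_px)))
    w = 2 * half + 1
    flat_img = images.reshape(-1)
    for lo in range(0, len(inst_frame), 20000):  # chunked to bound memory
        sl = slice(lo, lo + 20000)
        cr, cc, patches = _integrated_gaussian_patches(inst_x[sl], inst_y[sl],
                                                       inst_rate[sl], psf_sigma_px, half)
        rows = cr[:, None, None] + np.arange(w)[None, :, None]
        cols = cc[:, None, None] + np.arange(w)[None, None, :]
        ok = (rows >= 0) & (rows < H) & (cols >= 0) & (cols < W)
        flat = (inst_frame[sl][:, None, None] * (H * W)
                + np.clip(rows, 0, H - 1) * W + np.clip(cols, 0, W - 1))
        np.add.at(flat_img, flat[ok].ravel(), patches[ok].ravel())
    return images, frame_shape


def _ragged_arange(lengths: np.ndarray) -> np.ndarray:
    """[0..l0-1, 0..l1-1, ...] for an array of lengths."""
    total = int(lengths.sum())
    out = np.ones(total, dtype=np.int64)
    out[0] = 0
    ends = np.cumsum(lengths)[:-1]
    out[ends] = -(lengths[:-1] - 1)
    return np.cumsum(out)


def render_frames(events: BindingEvents, psf_sigma_px: float, camera: CameraModel,
                  seed: int = 0, bg_photons: float = 10.0,
                  frame_shape: tuple | None = None) -> FrameStack:
    """Render binding events into a 16-bit EMCCD frame stack.

    Noise chain per pixel: Poisson photoelectrons -> gamma EM amplification
    (shape = electrons, scale = em_gain) -> Gaussian read noise -> divide by
    sensitivity, add baseline, clip and quantize to uint16.  The ground-truth
    table of per-frame active emitters travels with the stack.
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be > 0")
    rng = substream(seed, "camera")
    expected, frame_shape = expected_photon_frames(events, psf_sigma_px, camera,
                                                   bg_photons, frame_shape)
    out = np.empty(expected.shape, dtype=np.uint16)
    for i in range(expected.shape[0]):  # frame-wise to bound memory
        electrons = rng.poisson(expected[i] * camera.quantum_efficiency).astype(np.float64)
        amplified = rng.standard_gamma(electrons) * camera.em_gain
        signal = amplified + rng.normal(0.0, camera.read_noise_e, size=electrons.shape)
        adu = signal * camera.preamp_gain / camera.sensitivity + camera.baseline_offset
        out[i] = np.clip(np.round(adu), 0, 65535).astype(np.uint16)

    true_locs = _events_truth_table(events, camera, frame_shape, bg_photons, psf_sigma_px)
    return FrameStack(frames=out, camera=camera, true_locs=true_locs)


def _events_truth_table(events, camera, frame_shape, bg_photons, psf_sigma_px):
    px_nm = camera.pixel_size_nm
    if len(events) == 0:
        return LocalizationTable.from_arrays(pixel_size_nm=px_nm, source="simulated-truth")
    dur = (events.end_frame - events.start_frame + 1).astype(np.int64)
    frames = np.repeat(events.start_frame, dur) + _ragged_arange(dur)
    x = np.repeat(events.x_nm / px_nm, dur)
    y = np.repeat(events.y_nm / px_nm, dur)
    rate = np.repeat(events.photon_rate, dur)
    H, W = frame_shape
    inside = (x >= 0) & (x < W) & (y >= 0) & (y < H)
    return LocalizationTable.from_arrays(
        frame=frames[inside], x=x[inside], y=y[inside], photons=rate[inside],
        sx=psf_sigma_px, sy=psf_sigma_px, bg=bg_photons, lpx=0.01, lpy=0.01,
        pixel_size_nm=px_nm, source="simulated-truth")


def apply_drift(stack: FrameStack, drift_trajectory_px: np.ndarray) -> FrameStack:
    """Shift frame i by trajectory[i] = (dx, dy) px via subpixel interpolation.

    The ground-truth localizations are shifted identically so that drift
    correction can be validated against truth.
    """
    traj = np.asarray(drift_trajectory_px, dtype=np.float64)
    if traj.shape != (stack.n_frames, 2):
        raise ValueError("trajectory must be (n_frames, 2)")
    out = np.empty_like(stack.frames)
    for i in range(stack.n_frames):
        dx, dy = traj[i]
        shifted = ndimage.shift(stack.frames[i].astype(np.float64), (dy, dx),
                                order=1, mode="nearest")
        out[i] = np.clip(np.round(shifted), 0, 65535).astype(np.uint16)
    locs = None
    if stack.true_locs is not None:
        df = stack.true_locs.df.copy()
        f = df["frame"].to_numpy()
        df["x"] = df["x"].to_numpy() + traj[f, 0]
        df["y"] = df["y"].to_numpy() + traj[f, 1]
        locs = stack.true_locs.copy_with(df, note="apply_drift")
    return FrameStack(frames=out, camera=stack.camera, true_locs=locs)
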