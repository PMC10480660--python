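"""File formats: TIFF stacks, Picasso-dialect HDF5 localization tables,
training patch sets and model checkpoints.

Localization tables are stored as an HDF5 record dataset named ``locs`` with
columns (frame, x, y, photons, sx, sy, bg, lpx, lpy, ...) plus a YAML sidecar
carrying the pixel size and processing history — the interchange layout used
by the Picasso software family — with an equivalent CSV mirror.  Stacks are
ImageJ-style 16-bit TIFF with a YAML sidecar for camera metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import LOC_COLUMNS, CameraModel, FrameStack, LocalizationTable


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".yaml")


# ---------------------------------------------------------------------------
# frame stacks
# ---------------------------------------------------------------------------

def write_stack(path, stack: FrameStack) -> None:
    """Write a 16-bit ImageJ-compatible TIFF plus a YAML metadata sidecar."""
    path = Path(path)
    frames = np.asarray(stack.frames)
    if frames.dtype != np.uint16:
        raise ValueError("stack frames must be uint16")
    tifffile.imwrite(path, frames, imagej=True,
                     resolution=(1e4 / (stack.camera.pixel_size_nm / 10),) * 2,
                     metadata={"unit": "um", "axes": "TYX"})
    meta = {"camera": {k: float(v) for k, v in vars(stack.camera).items()},
            "n_frames": int(stack.n_frames)}
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


def read_stack(path, camera: CameraModel | None = None) -> FrameStack:
    """Read a TIFF stack; camera metadata comes from the YAML sidecar
    (defaults with a warning when the sidecar is missing)."""
    import warnings

    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.dtype != np.uint16:
        raise ValueError(f"expected 16-bit unsigned TIFF, got {frames.dtype}")
    if camera is None:
        sc = _sidecar_path(path)
        if sc.exists():
            meta = yaml.safe_load(sc.read_text())
            camera = CameraModel(**meta.get("camera", {}))
        else:
            warnings.warn(f"no sidecar for {path}; using default camera metadata")
            camera = CameraModel()
    return FrameStack(frames=frames, camera=camera)


def iter_frames(path, chunk: int = 100):
    """Stream frames from a TIFF without loading the whole stack.

    Yields (start_index, array) blocks of at most ``chunk`` frames; memory use
    is bounded by the chunk size.
    """
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        n = series.shape[0] if len(series.shape) == 3 else 1
        pages = series.pages
        for lo in range(0, n, chunk):
            block = np.stack([pages[i].asarray() for i in range(lo, min(lo + chunk, n))])
            yield lo, block


# ---------------------------------------------------------------------------
# localization tables
# ---------------------------------------------------------------------------

def write_locs(path, table: LocalizationTable) -> None:
    """Write a localization table as Picasso-dialect HDF5 ("locs" record
    dataset) with a YAML sidecar."""
    path = Path(path)
    df = table.df
    extra = [c for c in df.columns if c not in LOC_COLUMNS]
    cols = LOC_COLUMNS + extra
    dtypes = []
    for c in cols:
        if c in ("frame", "link_id", "n_events"):
            dtypes.append((c, "i4"))
        else:
            dtypes.append((c, "f4"))
    rec = np.zeros(len(df), dtype=dtypes)
    for c in cols:
        rec[c] = df[c].to_numpy()
    with h5py.File(path, "w") as f:
        f.create_dataset("locs", data=rec)
    meta = {"pixel_size_nm": float(table.pixel_size_nm), "source": table.source,
            "history": list(table.history), "n_locs": int(len(df))}
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


def read_locs(path) -> LocalizationTable:
    """Read a Picasso-dialect HDF5 localization file (+ optional sidecar)."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "locs" not in f:
            raise ValueError("missing 'locs' dataset")
        rec = f["locs"][()]
    missing = [c for c in LOC_COLUMNS if c not in rec.dtype.names]
    if missing:
        raise ValueError(f"localization file missing columns: {missing}")
    df = pd.DataFrame({c: rec[c] for c in rec.dtype.names})
    df["frame"] = df["frame"].astype(np.int64)
    pixel_size, source, history = 157.0, str(path), []
    sc = _sidecar_path(path)
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}
        pixel_size = float(meta.get("pixel_size_nm", pixel_size))
        source = meta.get("source", source)
        history = list(meta.get("history", []))
    table = LocalizationTable(df=df, pixel_size_nm=pixel_size, source=source)
    table.history.extend(history)
    return table


def write_locs_csv(path, table: LocalizationTable) -> None:
    """CSV mirror of the HDF5 layout (identical columns and values)."""
    df = table.df
    cols = LOC_COLUMNS + [c for c in df.columns if c not in LOC_COLUMNS]
    out = df[cols].copy()
    for c in cols:
        if c not in ("frame", "link_id", "n_events"):
            out[c] = out[c].astype(np.float32)
    out.to_csv(path, index=False)


def read_locs_csv(path, pixel_size_nm: float = 157.0) -> LocalizationTable:
    df = pd.read_csv(path)
    missing = [c for c in LOC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"localization CSV missing columns: {missing}")
    df["frame"] = df["frame"].astype(np.int64)
    for c in df.columns:
        if c not in ("frame", "link_id", "n_events"):
            # restore the float32 storage precision of the HDF5 layout
            df[c] = df[c].astype(np.float32)
    return LocalizationTable(df=df, pixel_size_nm=pixel_size_nm, source=str(path))


# ---------------------------------------------------------------------------
# training patch sets
# ---------------------------------------------------------------------------

def write_patches(path, patch_set) -> None:
    """Patch set as one HDF5 file: 'patches' (n, P, P), ragged labels via
    offset + coordinate arrays, meta as attributes."""
    offsets = np.zeros(len(patch_set) + 1, dtype=np.int64)
    for i, lab in enumerate(patch_set.labels):
        offsets[i + 1] = offsets[i] + len(lab)
    xy = (np.concatenate([np.asarray(l).reshape(-1, 2) for l in patch_set.labels])
          if offsets[-1] else np.empty((0, 2)))
    with h5py.File(path, "w") as f:
        f.create_dataset("patches", data=patch_set.patches, compression="gzip")
        f.create_dataset("label_offsets", data=offsets)
        f.create_dataset("label_xy", data=xy)
        for k, v in patch_set.meta.items():
            f.attrs[k] = json.dumps(v) if isinstance(v, (list, tuple, dict)) else v


def read_patches(path):
    from .densitydata import TrainingPatchSet

    with h5py.File(path, "r") as f:
        patches = f["patches"][()]
        offsets = f["label_offsets"][()]
        xy = f["label_xy"][()]
        meta = {}
        for k, v in f.attrs.items():
            if isinstance(v, str) and v[:1] in "[{":
                v = json.loads(v)
            meta[k] = v
    labels = [xy[offsets[i]:offsets[i + 1]] for i in range(len(patches))]
    return TrainingPatchSet(patches=patches, labels=labels, meta=meta)


# ---------------------------------------------------------------------------
# model checkpoints
# ---------------------------------------------------------------------------

def save_model(path, model) -> None:
    """Single-archive checkpoint: weights, batch-norm statistics,
    normalization constants, config and history."""
    from dataclasses import asdict

    arrays = {}
    for li, layer in enumerate(model.layers):
        for pi, (p, _) in enumerate(layer.params()):
            arrays[f"layer{li}_p{pi}"] = p
        if hasattr(layer, "running_mean"):
            arrays[f"layer{li}_rmean"] = layer.running_mean
            arrays[f"layer{li}_rvar"] = layer.running_var
    cfg = asdict(model.config)
    cfg["widths"] = list(cfg["widths"])
    meta = dict(config=cfg, norm_mean=model.norm_mean, norm_std=model.norm_std,
                history=model.history)
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_model(path):
    from .deepdense import TrainConfig, build_model

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        cfg = meta["config"]
        cfg["widths"] = tuple(cfg["widths"])
        model = build_model(TrainConfig(**cfg))
        for li, layer in enumerate(model.layers):
            for pi, (p, _) in enumerate(layer.params()):
                p[...] = z[f"layer{li}_p{pi}"]
            if hasattr(layer, "running_mean"):
                layer.running_mean = z[f"layer{li}_rmean"]
                layer.running_var = z[f"layer{li}_rvar"]
    model.norm_mean = float(meta["norm_mean"])
    model.norm_std = float(meta["norm_std"])
    model.history = meta["history"]
    return model
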