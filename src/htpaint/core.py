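"""Shared containers and conventions for the HT-PAINT pipeline.

Coordinate convention
---------------------
Localization coordinates are continuous camera-pixel units with the origin at
the outer corner of pixel (0, 0): a coordinate of ``x`` lies inside pixel
``floor(x)``, x increases to the right (columns), y increases downward (rows).
Conversions to nanometers happen only at render time via ``pixel_size_nm``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: canonical localization-table columns, in interchange order
LOC_COLUMNS = ["frame", "x", "y", "photons", "sx", "sy", "bg", "lpx", "lpy"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from one global seed.

    The substream key is a stable hash of ``name`` so re-running a single
    pipeline stage in isolation reproduces its outputs.
    """
    digest = hashlib.blake2b(name.encode(), digest_size=4).digest()
    key = int.from_bytes(digest, "little") & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def substream_seed(seed: int, name: str) -> int:
    """A plain integer seed (< 2**31) for the named substream."""
    digest = hashlib.blake2b(name.encode(), digest_size=4).digest()
    key = int.from_bytes(digest, "little") & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class CameraModel:
    """EMCCD camera forward/inverse model.

    The signal chain for an expected photon count n per pixel is
    Poisson(n * quantum_efficiency) photoelectrons, stochastic electron
    multiplication (gamma with shape = electrons, scale = em_gain), additive
    Gaussian read noise, division by ``sensitivity`` (e-/ADU) and the
    ``baseline_offset`` in ADU.  Defaults follow a back-illuminated EMCCD
    operated at EM gain 50, preamp gain 1, 5 MHz readout, 157 nm pixels.
    """

    pixel_size_nm: float = 157.0
    integration_time_ms: float = 150.0
    em_gain: float = 50.0
    preamp_gain: float = 1.0
    quantum_efficiency: float = 0.9
    read_noise_e: float = 60.0
    baseline_offset: float = 100.0
    sensitivity: float = 12.0  # e-/ADU

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        for name in ("em_gain", "preamp_gain", "sensitivity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.quantum_efficiency <= 1:
            raise ValueError("quantum_efficiency must be in (0, 1]")

    @property
    def adu_per_photon(self) -> float:
        """Expected ADU above baseline produced by one incident photon."""
        return self.quantum_efficiency * self.em_gain * self.preamp_gain / self.sensitivity

    def adu_to_photons(self, adu: np.ndarray) -> np.ndarray:
        """Invert the mean camera response (baseline-subtract and rescale)."""
        return (np.asarray(adu, dtype=np.float64) - self.baseline_offset) / self.adu_per_photon

    def photons_to_adu_mean(self, photons: np.ndarray) -> np.ndarray:
        return np.asarray(photons, dtype=np.float64) * self.adu_per_photon + self.baseline_offset


@dataclass
class LocalizationTable:
    """Per-emitter localization records with camera metadata.

    ``df`` holds at least the columns in :data:`LOC_COLUMNS`; linking adds
    ``link_id`` and ``n_events``.  Positions are camera pixels (corner-origin,
    see module docstring), ``bg`` is photons per pixel, ``lpx``/``lpy`` are
    Cramer-Rao-type per-axis precisions in pixels.
    """

    df: pd.DataFrame
    pixel_size_nm: float = 157.0
    source: str = ""
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in LOC_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"localization table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    def copy_with(self, df: pd.DataFrame, note: str | None = None) -> "LocalizationTable":
        out = replace(self, df=df, history=list(self.history))
        if note:
            out.history.append(note)
        return out

    @classmethod
    def from_arrays(cls, pixel_size_nm: float = 157.0, source: str = "", **cols) -> "LocalizationTable":
        n = len(cols.get("x", []))
        data = {}
        defaults = dict(frame=0, x=0.0, y=0.0, photons=1.0, sx=1.0, sy=1.0,
                        bg=0.0, lpx=0.1, lpy=0.1)
        for c in LOC_COLUMNS:
            v = cols.get(c, defaults[c])
            data[c] = np.broadcast_to(np.asarray(v), (n,)).copy()
        for c, v in cols.items():
            if c not in LOC_COLUMNS:
                data[c] = np.broadcast_to(np.asarray(v), (n,)).copy()
        df = pd.DataFrame(data)
        df["frame"] = df["frame"].astype(np.int64)
        return cls(df=df, pixel_size_nm=pixel_size_nm, source=source)


@dataclass
class FrameStack:
    """Ordered raw camera frames (n_frames, H, W) as unsigned 16-bit ADU."""

    frames: np.ndarray
    camera: CameraModel = field(default_factory=CameraModel)
    true_locs: LocalizationTable | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be (n_frames, H, W) with n_frames >= 1")
        if self.true_locs is not None and len(self.true_locs):
            if int(self.true_locs.df["frame"].max()) >= self.n_frames:
                raise ValueError("true_locs frame indices exceed n_frames")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple:
        return tuple(self.frames.shape)

    def photons(self, frames: slice | None = None) -> np.ndarray:
        """Photon-converted view of (a slice of) the stack."""
        sel = self.frames if frames is None else self.frames[frames]
        return self.camera.adu_to_photons(sel)
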