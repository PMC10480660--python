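"""Acquisition profiles for the HT-PAINT acceleration experiments.

Each profile describes one imaging experiment: the ground-truth acquisition
(long, low emitter density, localized frame by frame) and the accelerated
high-density acquisition reconstructed by the network.  The derived
quantities — acceleration factor, predicted pixel size, movie timing — follow
from these numbers and the camera settings.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AcquisitionProfile:
    """One target/imaging-mode combination of the acceleration workflow."""

    name: str
    target: str
    mode: str                  # "fixed" or "live"
    gt_frames: int | None      # low-density ground-truth acquisition length
    hd_frames: int             # high-density (accelerated) acquisition length
    integration_time_ms: float
    upsampling: int
    pixel_size_nm: float = 157.0
    gt_density_um2: float = 0.109   # emitters / um^2 / frame
    hd_density_um2: float = 1.3

    @property
    def acceleration_factor(self) -> float:
        """Ratio of ground-truth to prediction acquisition length."""
        if self.gt_frames is None:
            raise ValueError(f"profile {self.name} has no ground-truth acquisition")
        return self.gt_frames / self.hd_frames

    @property
    def predicted_pixel_nm(self) -> float:
        """Pixel size of the predicted super-resolution grid."""
        return self.pixel_size_nm / self.upsampling

    @property
    def acquisition_duration_min(self) -> float:
        """Total high-density acquisition time in minutes."""
        return self.hd_frames * self.integration_time_ms / 1e3 / 60.0


#: fixed-cell single-target experiments (upsampling 16 -> ~10 nm grid)
VIMENTIN_FIXED = AcquisitionProfile(
    name="vimentin-fixed", target="vimentin", mode="fixed",
    gt_frames=25000, hd_frames=1000, integration_time_ms=150.0, upsampling=16)
TOM20_FIXED = AcquisitionProfile(
    name="tom20-fixed", target="TOM20 (mitochondria)", mode="fixed",
    gt_frames=20000, hd_frames=1000, integration_time_ms=150.0, upsampling=16)
CALR_FIXED = AcquisitionProfile(
    name="calr-kdel-fixed", target="CalR-KDEL (ER)", mode="fixed",
    gt_frames=25000, hd_frames=1000, integration_time_ms=150.0, upsampling=16)

#: live-cell ER dynamics (upsampling 8 -> ~20 nm grid, sliding-window movie)
ER_LIVE = AcquisitionProfile(
    name="calr-kdel-live", target="CalR-KDEL (ER)", mode="live",
    gt_frames=None, hd_frames=15000, integration_time_ms=50.0, upsampling=8)

PROFILES = {p.name: p for p in (VIMENTIN_FIXED, TOM20_FIXED, CALR_FIXED, ER_LIVE)}


def movie_temporal_spacing_s(step_frames: int, integration_time_ms: float) -> float:
    """Time between consecutive movie frames for a sliding-window step."""
    return step_frames * integration_time_ms / 1e3
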