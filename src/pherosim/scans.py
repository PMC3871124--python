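"""1-D fluorescence intensity profiles from compartment scan images.

A low-resolution scanner image of the reporter compartment is reduced to
a profile of mean intensity versus distance from the compartment
boundary, normalized so that 1.0 corresponds to the plateau of a
constitutively fluorescent reference compartment.  The profile summary
statistics are the detection extent (farthest distance still above a
relative threshold) and the peak position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import medfilt

from .diffusion import InvalidParameterError

__all__ = [
    "ScanImage",
    "RawProfile",
    "FluorescenceProfile",
    "plot_profile",
    "estimate_background",
    "normalize_profile",
    "detection_extent",
    "peak_position",
]

_EDGES = ("left", "right", "top", "bottom")

#: Median-filter window (samples) applied before extent/peak calls.
SMOOTH_WINDOW = 3


@dataclass
class ScanImage:
    """Scanner image with compartment ROI and boundary-edge annotation.

    ``roi`` is (row_start, row_stop, col_start, col_stop) in pixels;
    ``boundary_edge`` names the ROI edge abutting the source compartment,
    so profile distances run from that edge inward.
    """

    image: np.ndarray
    pixel_size_mm: float
    roi: tuple[int, int, int, int]
    boundary_edge: str = "left"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise InvalidParameterError("scan image must be 2-D")
        if self.pixel_size_mm <= 0:
            raise InvalidParameterError("pixel_size_mm must be > 0")
        r0, r1, c0, c1 = self.roi
        nr, nc = self.image.shape
        if not (0 <= r0 < r1 <= nr and 0 <= c0 < c1 <= nc):
            raise InvalidParameterError(f"ROI {self.roi} outside image of shape {self.image.shape}")
        if self.boundary_edge not in _EDGES:
            raise InvalidParameterError(f"boundary_edge must be one of {_EDGES}")


@dataclass
class RawProfile:
    """Un-normalized mean-intensity profile versus distance (mm)."""

    distances: np.ndarray
    intensity: np.ndarray


@dataclass
class FluorescenceProfile:
    """Background-corrected profile relative to the constitutive reference."""

    distances: np.ndarray
    relative_intensity: np.ndarray
    reference_value: float

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.relative_intensity = np.asarray(self.relative_intensity, dtype=float)
        if np.any(np.diff(self.distances) <= 0):
            raise InvalidParameterError("distances must be strictly increasing")
        if np.any(self.relative_intensity < 0):
            raise InvalidParameterError("relative intensity must be nonnegative")


def plot_profile(scan: ScanImage) -> RawProfile:
    """Mean intensity across the transverse ROI extent, per pixel of depth.

    The distance axis starts at the boundary edge and runs inward; each
    sample is the mean over the ROI's transverse direction, i.e. the
    scan-image equivalent of a rectangular line-profile.
    """
    r0, r1, c0, c1 = scan.roi
    block = scan.image[r0:r1, c0:c1]
    if scan.boundary_edge in ("top", "bottom"):
        block = block.T
        if scan.boundary_edge == "bottom":
            block = block[:, ::-1]
    elif scan.boundary_edge == "right":
        block = block[:, ::-1]
    intensity = block.mean(axis=0)
    distances = (np.arange(intensity.size) + 0.5) * scan.pixel_size_mm
    return RawProfile(distances=distances, intensity=intensity)


def estimate_background(scan: ScanImage, blank_roi: tuple[int, int, int, int]) -> float:
    """Mean intensity of a cell-free region of the scan."""
    r0, r1, c0, c1 = blank_roi
    nr, nc = scan.image.shape
    if not (0 <= r0 < r1 <= nr and 0 <= c0 < c1 <= nc):
        raise InvalidParameterError("blank ROI outside image")
    return float(scan.image[r0:r1, c0:c1].mean())


def normalize_profile(
    raw: RawProfile, reference_value: float, background: float = 0.0
) -> FluorescenceProfile:
    """Scale a raw profile so the constitutive reference maps to 1.0.

    relative = (raw - background) / (reference - background); negative
    values from noise below background are clamped at zero.
    """
    if reference_value <= background:
        raise InvalidParameterError(
            f"reference ({reference_value}) must exceed background ({background})"
        )
    rel = (raw.intensity - background) / (reference_value - background)
    return FluorescenceProfile(
        distances=raw.distances.copy(),
        relative_intensity=np.clip(rel, 0.0, None),
        reference_value=reference_value,
    )


def _smoothed(profile: FluorescenceProfile) -> np.ndarray:
    if profile.relative_intensity.size >= SMOOTH_WINDOW:
        return medfilt(profile.relative_intensity, SMOOTH_WINDOW)
    return profile.relative_intensity


def detection_extent(profile: FluorescenceProfile, rel_threshold: float = 0.05) -> float:
    """Farthest distance (mm) with median-smoothed relative intensity >= threshold."""
    if profile.distances.size == 0:
        raise InvalidParameterError("profile is empty")
    smooth = _smoothed(profile)
    hit = np.flatnonzero(smooth >= rel_threshold)
    if hit.size == 0:
        return 0.0
    return float(profile.distances[hit[-1]])


def peak_position(profile: FluorescenceProfile) -> float:
    """Distance (mm) of the smoothed profile maximum; ties resolve boundary-ward."""
    if profile.distances.size == 0:
        raise InvalidParameterError("profile is empty")
    smooth = _smoothed(profile)
    return float(profile.distances[int(np.argmax(smooth))])
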