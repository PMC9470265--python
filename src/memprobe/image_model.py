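"""Hyperspectral microscopy stacks for solvatochromic membrane probes.

A spectral image is a stack of emission channels (channel x row x col)
acquired simultaneously on an array detector, each channel integrating a
~9 nm wavelength window. This module holds the in-memory container plus the
spectral bookkeeping every downstream step relies on: mapping wavelengths to
detector channels, background correction against a dark region of interest,
and extraction of (optionally normalized) emission spectra from labelled
regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SpectralImage",
    "ROI",
    "EmissionSpectrum",
    "channel_for_wavelength",
    "subtract_background",
    "extract_spectrum",
    "read_spectral_tiff",
    "write_spectral_tiff",
]


@dataclass
class SpectralImage:
    """Emission-channel intensity stack with per-channel wavelength centers.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_rows, n_cols)
        Detector intensities, arbitrary units. Finite; nonnegative after
        background correction (raw data may contain zeros).
    channel_centers : ndarray, shape (n_channels,)
        Center wavelength of each detection channel in nm, strictly
        increasing and approximately uniformly spaced.
    """

    data: np.ndarray
    channel_centers: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_centers = np.asarray(self.channel_centers, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (channel, row, col)")
        if self.channel_centers.ndim != 1 or len(self.channel_centers) != self.data.shape[0]:
            raise ValueError("channel_centers must match the number of channel planes")
        if not np.all(np.diff(self.channel_centers) > 0):
            raise ValueError("channel_centers must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (rows, cols) shape."""
        return self.data.shape[1:]

    @property
    def spacing(self) -> float:
        """Mean channel spacing in nm."""
        return float(np.mean(np.diff(self.channel_centers)))

    def total_intensity(self) -> np.ndarray:
        """Sum over channels; the field used for segmentation."""
        return self.data.sum(axis=0)


@dataclass
class ROI:
    """A set of (row, col) pixels with a free-text label."""

    pixels: np.ndarray  # (n, 2) int array of (row, col)
    label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.atleast_2d(np.asarray(self.pixels, dtype=int))
        if self.pixels.size == 0:
            raise ValueError("ROI must contain at least one pixel")
        if self.pixels.shape[1] != 2:
            raise ValueError("ROI pixels must be (row, col) pairs")

    @classmethod
    def from_mask(cls, mask: np.ndarray, label: str = "") -> "ROI":
        return cls(np.argwhere(np.asarray(mask, dtype=bool)), label=label)

    def validate_bounds(self, shape: tuple[int, int]) -> None:
        r, c = self.pixels[:, 0], self.pixels[:, 1]
        if r.min() < 0 or c.min() < 0 or r.max() >= shape[0] or c.max() >= shape[1]:
            raise ValueError(f"ROI {self.label!r} exceeds image bounds {shape}")

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass
class EmissionSpectrum:
    """Wavelength-resolved emission intensities.

    If ``normalized`` is set, intensities are scaled so the maximum is 1.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must have the same length")
        if self.normalized and not np.isclose(self.intensities.max(), 1.0):
            raise ValueError("normalized spectrum must peak at 1")

    def interpolate(self, wavelengths: np.ndarray) -> np.ndarray:
        """Linear interpolation onto another wavelength grid."""
        return np.interp(wavelengths, self.wavelengths, self.intensities)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "intensity": self.intensities}
        )
        peak = self.intensities.max()
        df["normalized_intensity"] = self.intensities / peak if peak > 0 else np.nan
        return df


def channel_for_wavelength(img: SpectralImage, wavelength: float) -> int:
    """Index of the detection channel whose center is nearest ``wavelength``.

    Ties between two equidistant centers resolve toward the bluer (lower
    index) channel. Wavelengths further than one channel spacing outside the
    grid are rejected.
    """
    centers = img.channel_centers
    spacing = img.spacing
    if not (centers[0] - spacing <= wavelength <= centers[-1] + spacing):
        raise ValueError(
            f"wavelength {wavelength} nm outside tolerated range "
            f"[{centers[0] - spacing:.1f}, {centers[-1] + spacing:.1f}]"
        )
    # argmin returns the first minimum -> blue-ward tie break for free
    return int(np.argmin(np.abs(centers - wavelength)))


def subtract_background(img: SpectralImage, bg: ROI) -> SpectralImage:
    """Subtract the per-channel mean over a background ROI; clamp at zero.

    The background is a single scalar per channel (the Z-profile of the
    background region), not a per-pixel field. Negative corrected
    intensities are clamped to 0 so downstream intensity ratios stay in
    their physical range.
    """
    bg.validate_bounds(img.shape)
    r, c = bg.pixels[:, 0], bg.pixels[:, 1]
    bg_profile = img.data[:, r, c].mean(axis=1)  # (n_channels,)
    corrected = img.data - bg_profile[:, None, None]
    np.clip(corrected, 0.0, None, out=corrected)
    return SpectralImage(corrected, img.channel_centers.copy())


def extract_spectrum(img: SpectralImage, roi: ROI, normalize: bool = True) -> EmissionSpectrum:
    """Mean per-channel intensity over an ROI, optionally peak-normalized."""
    roi.validate_bounds(img.shape)
    r, c = roi.pixels[:, 0], roi.pixels[:, 1]
    intensities = img.data[:, r, c].mean(axis=1)
    if normalize:
        peak = intensities.max()
        if peak <= 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        intensities = intensities / peak
    return EmissionSpectrum(img.channel_centers.copy(), intensities, normalized=normalize)


def write_spectral_tiff(img: SpectralImage, path: str | Path) -> None:
    """Multi-page TIFF (one page per channel) + sidecar JSON of centers."""
    path = Path(path)
    tifffile.imwrite(path, img.data.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"channel_centers_nm": img.channel_centers.tolist()}))


def read_spectral_tiff(path: str | Path) -> SpectralImage:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar = path.with_suffix(path.suffix + ".json")
    centers = json.loads(sidecar.read_text())["channel_centers_nm"]
    return SpectralImage(np.asarray(data, dtype=float), np.asarray(centers, dtype=float))
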