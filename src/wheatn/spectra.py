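"""Reflectance spectra, empirical-line DN calibration and AOI aggregation.

Canopy reflectance comes as a complete 1 nm grid (350–2500 nm by default).
RGB imagery arrives as raw digital numbers (DNs); the empirical line method
maps them to a calibrated 0–255 scale using in-scene white and black
reference panels:

    DN_cal = (DN_object − DN_black) / (DN_white − DN_black) × 255

applied per band with that band's panel DNs.  Plot statistics are arithmetic
means of the pixel DNs inside an area of interest (AOI); resampling follows a
nearest-neighbor contract (each output pixel takes the value of the nearest
input pixel center, no interpolation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ReflectanceSpectrum:
    """Wavelength-indexed canopy reflectance on a complete 1 nm integer grid."""

    wavelengths: np.ndarray  # nm, strictly increasing integers, no gaps
    values: np.ndarray  # reflectance fraction in [0, 1]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must have equal length")
        if self.wavelengths.size < 2:
            raise ValueError("spectrum needs at least two samples")
        diffs = np.diff(self.wavelengths)
        if not np.all(diffs == 1):
            raise ValueError("wavelength grid must be a gapless 1 nm integer grid")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("reflectance values must lie in [0, 1]")

    @property
    def wl_min(self) -> int:
        return int(self.wavelengths[0])

    @property
    def wl_max(self) -> int:
        return int(self.wavelengths[-1])

    def band(self, wavelength: float) -> float:
        """Reflectance at ``wavelength`` (nm).

        Exact grid value at integer nm; linear interpolation between grid
        points otherwise.  Out-of-range requests raise ``ValueError``.
        """
        return band(self, wavelength)

    def covers(self, lo: float, hi: float) -> bool:
        return self.wl_min <= lo and hi <= self.wl_max


def band(spectrum: ReflectanceSpectrum, wavelength: float) -> float:
    """Reflectance of ``spectrum`` at ``wavelength`` nm (linear interpolation)."""
    if not spectrum.wl_min <= wavelength <= spectrum.wl_max:
        raise ValueError(
            f"wavelength {wavelength} nm outside spectrum range "
            f"[{spectrum.wl_min}, {spectrum.wl_max}] nm"
        )
    idx = wavelength - spectrum.wl_min
    lo = int(np.floor(idx))
    frac = idx - lo
    if frac == 0:
        return float(spectrum.values[lo])
    return float((1 - frac) * spectrum.values[lo] + frac * spectrum.values[lo + 1])


@dataclass
class RGBPlotStats:
    """Per-band mean DN over an AOI plus the panel DNs used for calibration."""

    mean_dn: dict[str, float]  # band -> mean DN over the AOI
    white_dn: dict[str, float]  # band -> white panel DN
    black_dn: dict[str, float]  # band -> black panel DN
    calibrated: bool = False
    n_clamped: int = 0
    stage: str = ""
    plot_id: object = None

    BANDS = ("R", "G", "B")

    def __post_init__(self) -> None:
        for b in self.mean_dn:
            if b in self.white_dn and b in self.black_dn:
                if not self.white_dn[b] > self.black_dn[b]:
                    raise ValueError(f"white panel DN must exceed black panel DN for band {b}")

    def calibrate(self) -> "RGBPlotStats":
        """Empirical-line calibrate every band; returns a new calibrated record."""
        if self.calibrated:
            return self
        out: dict[str, float] = {}
        clamped = 0
        for b, dn in self.mean_dn.items():
            val, c = calibrate_dn(dn, self.white_dn[b], self.black_dn[b], count_clamped=True)
            out[b] = val
            clamped += c
        return RGBPlotStats(
            mean_dn=out,
            white_dn=self.white_dn,
            black_dn=self.black_dn,
            calibrated=True,
            n_clamped=clamped,
            stage=self.stage,
            plot_id=self.plot_id,
        )


def calibrate_dn(dn_object, dn_white, dn_black, *, clamp: bool = True, count_clamped: bool = False):
    """Empirical-line calibration of raw DNs against white/black panels.

    ``(dn_object − dn_black) / (dn_white − dn_black) × 255``; affine and
    monotone in ``dn_object``.  Outputs outside [0, 255] are clamped (with a
    logged count) only at output.
    """
    dn_object = np.asarray(dn_object, dtype=float)
    if not np.all(np.asarray(dn_white) > np.asarray(dn_black)):
        raise ValueError("white panel DN must exceed black panel DN")
    cal = (dn_object - dn_black) / (dn_white - dn_black) * 255.0
    n_clamped = 0
    if clamp:
        outside = (cal < 0) | (cal > 255)
        n_clamped = int(np.count_nonzero(outside))
        if n_clamped:
            logger.warning("calibrate_dn clamped %d value(s) to [0, 255]", n_clamped)
        cal = np.clip(cal, 0.0, 255.0)
    result = float(cal) if cal.ndim == 0 else cal
    if count_clamped:
        return result, n_clamped
    return result


def aoi_aggregate(
    pixel_dn: dict[str, np.ndarray],
    mask: np.ndarray,
    white_dn: dict[str, float],
    black_dn: dict[str, float],
    *,
    stage: str = "",
    plot_id=None,
) -> RGBPlotStats:
    """Mean raw DN per band over the masked AOI pixels.

    ``pixel_dn`` maps band name to a 2-D DN array; ``mask`` is a boolean
    array of the same shape selecting at least one AOI pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("AOI mask selects no pixels")
    means: dict[str, float] = {}
    for b, img in pixel_dn.items():
        img = np.asarray(img, dtype=float)
        if img.shape != mask.shape:
            raise ValueError(f"band {b} image shape {img.shape} != mask shape {mask.shape}")
        means[b] = float(img[mask].mean())
    return RGBPlotStats(
        mean_dn=means, white_dn=dict(white_dn), black_dn=dict(black_dn), stage=stage, plot_id=plot_id
    )


def nearest_neighbor_resample(image: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Resample a 2-D image to ``out_shape`` by the nearest-neighbor rule.

    Each output pixel takes the value of the input pixel whose center is
    nearest to the output pixel center (no interpolation); constants map to
    constants at any scale.
    """
    image = np.asarray(image)
    in_h, in_w = image.shape
    out_h, out_w = out_shape
    # pixel centers at (i + 0.5) / n in unit coordinates
    rows = np.clip(np.floor((np.arange(out_h) + 0.5) * in_h / out_h), 0, in_h - 1).astype(int)
    cols = np.clip(np.floor((np.arange(out_w) + 0.5) * in_w / out_w), 0, in_w - 1).astype(int)
    return image[np.ix_(rows, cols)]
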