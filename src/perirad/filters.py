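"""Derived image types: intensity remaps, Laplacian of Gaussian, wavelet bands.

The default configuration produces 13 derived volumes which, together with
the original, give the 14 image types feeding feature extraction: four
monotone intensity remaps (square, square root, logarithm, exponential),
one LoG response at sigma = 3 mm, and the 8 sub-bands of a single-level
undecimated 3-D wavelet decomposition (coif1).  Filters act on the whole
volume; masks are applied only at feature time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pywt
from scipy import ndimage

from .image import Volume

WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
REMAP_NAMES = ("square", "squareroot", "logarithm", "exponential")

DEFAULT_LOG_SIGMA_MM = 3.0
DEFAULT_WAVELET = "coif1"


@dataclass(frozen=True)
class FilterConfig:
    """Which derived image types to compute.

    The defaults yield 13 derived types; with the original image, 14 types
    in total, which is what pins the 1,316-feature arithmetic
    (14 shape + 93 non-shape x 14).
    """

    remaps: tuple[str, ...] = REMAP_NAMES
    log_sigmas_mm: tuple[float, ...] = (DEFAULT_LOG_SIGMA_MM,)
    wavelet: str | None = DEFAULT_WAVELET

    def image_type_names(self) -> list[str]:
        names = ["original"]
        names += list(self.remaps)
        names += [f"log-sigma-{s:g}mm" for s in self.log_sigmas_mm]
        if self.wavelet is not None:
            names += [f"wavelet-{b}" for b in WAVELET_BANDS]
        return names


def apply_intensity_remap(volume: Volume, name: str) -> Volume:
    """Monotone pointwise remap, rescaled back onto the input range.

    With m = max|x|:
      square       y = (x / sqrt(m))^2 = x^2 / m
      squareroot   y = sqrt(m * x)
      logarithm    y = m * log(x + 1) / log(m + 1)
      exponential  y = exp(x * log(m) / m)

    Each maps m back to m and preserves intensity ordering on positive
    inputs (guaranteed after gray-value normalization to (1, 4097)).
    """
    x = volume.values
    m = float(np.abs(x).max())
    if m == 0:
        return volume
    if name == "square":
        y = (x / np.sqrt(m)) ** 2 * np.sign(x)
    elif name == "squareroot":
        y = np.sqrt(m * np.abs(x)) * np.sign(x)
    elif name == "logarithm":
        y = m * np.log(np.abs(x) + 1.0) / np.log(m + 1.0) * np.sign(x)
    elif name == "exponential":
        y = np.exp(np.abs(x) * np.log(m) / m) * np.sign(x) if m != 1.0 \
            else np.abs(x) * np.sign(x)
    else:
        raise ValueError(f"unknown intensity remap {name!r}")
    return replace(volume, values=y)


def apply_log_filter(volume: Volume, sigma_mm: float) -> Volume:
    """Laplacian-of-Gaussian response at physical scale sigma (mm).

    Requires an isotropic grid (resample first); the Gaussian width in
    voxels is sigma / spacing per axis.
    """
    if sigma_mm <= 0:
        raise ValueError(f"LoG sigma must be > 0 mm, got {sigma_mm}")
    sig_vox = [sigma_mm / s for s in volume.spacing]
    y = ndimage.gaussian_laplace(volume.values, sigma=sig_vox)
    return replace(volume, values=y)


def apply_wavelet(volume: Volume, basis: str = DEFAULT_WAVELET) -> dict[str, Volume]:
    """Single-level undecimated (stationary) 3-D wavelet decomposition.

    Returns the 8 sub-bands keyed LLL..HHH, each on the original grid so
    masks apply unchanged.  Axis order of the band label is (x, y, z).
    """
    x = volume.values
    w = pywt.Wavelet(basis)
    if min(x.shape) < w.dec_len:
        raise ValueError(
            f"grid {x.shape} too small for wavelet {basis} (filter length {w.dec_len})")
    # swtn requires even dimensions; pad by edge replication then crop.
    pads = [(0, s % 2) for s in x.shape]
    xp = np.pad(x, pads, mode="edge")
    coeffs = pywt.swtn(xp, w, level=1, start_level=0)[0]
    out: dict[str, Volume] = {}
    for band in WAVELET_BANDS:
        key = band.lower().replace("l", "a").replace("h", "d")
        sub = coeffs[key][: x.shape[0], : x.shape[1], : x.shape[2]]
        out[band] = replace(volume, values=sub)
    return out


def derive_images(volume: Volume, config: FilterConfig = FilterConfig()) -> dict[str, Volume]:
    """All configured image types keyed by name; includes ``original``."""
    out: dict[str, Volume] = {"original": volume}
    for name in config.remaps:
        out[name] = apply_intensity_remap(volume, name)
    for s in config.log_sigmas_mm:
        out[f"log-sigma-{s:g}mm"] = apply_log_filter(volume, s)
    if config.wavelet is not None:
        for band, vol in apply_wavelet(volume, config.wavelet).items():
            out[f"wavelet-{band}"] = vol
    return out
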