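"""Beat segment -> 32x32x3 scalogram image.

The scalogram is the matrix of absolute continuous-wavelet-transform
coefficients of the beat over a logarithmic frequency grid.  Default
analysis uses a complex Morlet wavelet with 12 voices per octave spanning
0.5-60 Hz at a 360 Hz sampling rate; the magnitude matrix is min-max
normalized per image, resized to 32x32 by bilinear interpolation
(align-corners=false), and mapped through a fixed 256-entry rainbow
lookup table shipped with the package, yielding an RGB image in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pywt

__all__ = [
    "ScalogramImage",
    "ScalogramConfig",
    "cwt_magnitude",
    "to_image",
    "segment_to_image",
    "load_colormap",
]

DEFAULT_WAVELET = "cmor1.5-1.0"
DEFAULT_FS = 360.0
DEFAULT_FMIN = 0.5
DEFAULT_FMAX = 60.0
DEFAULT_VOICES = 12  # scales per octave


@dataclass(frozen=True)
class ScalogramConfig:
    wavelet: str = DEFAULT_WAVELET
    fs: float = DEFAULT_FS
    fmin: float = DEFAULT_FMIN
    fmax: float = DEFAULT_FMAX
    voices_per_octave: int = DEFAULT_VOICES
    out_size: int = 32
    colormap: str = "jet256"
    normalization: str = "per-image min-max"

    def n_scales(self) -> int:
        octaves = np.log2(self.fmax / self.fmin)
        return int(np.ceil(octaves * self.voices_per_octave)) + 1


@dataclass(frozen=True)
class ScalogramImage:
    pixels: np.ndarray  # (out_size, out_size, 3), float32 in [0, 1]
    provenance: ScalogramConfig


_LUT_CACHE: dict[str, np.ndarray] = {}


def load_colormap(name: str = "jet256") -> np.ndarray:
    """Fixed 256x3 RGB lookup table stored as package data."""
    if name not in _LUT_CACHE:
        with resources.files("beatid.data").joinpath(f"{name}.csv").open("rb") as fh:
            lut = np.loadtxt(fh, delimiter=",", skiprows=1, dtype=np.float64)
        if lut.shape != (256, 3):
            raise ValueError(f"colormap {name!r} must be 256x3, got {lut.shape}")
        _LUT_CACHE[name] = lut
    return _LUT_CACHE[name]


def scale_grid(config: ScalogramConfig = ScalogramConfig()) -> tuple[np.ndarray, np.ndarray]:
    """(scales, center frequencies in Hz), frequencies descending.

    Frequencies are log-spaced with ``voices_per_octave`` points per octave
    from fmax down to fmin; scale = fc * fs / f with fc the wavelet's center
    frequency, so scales are ascending (low scale first = highest frequency).
    """
    n = config.n_scales()
    freqs = np.geomspace(config.fmax, config.fmin, n)
    fc = pywt.central_frequency(config.wavelet)
    scales = fc * config.fs / freqs
    return scales, freqs


def cwt_magnitude(
    segment: np.ndarray, config: ScalogramConfig = ScalogramConfig()
) -> np.ndarray:
    """|CWT| of a beat: (n_scales, n_samples), small scales in the first rows."""
    segment = np.asarray(segment, dtype=np.float64)
    if segment.ndim != 1 or segment.size < 8:
        raise ValueError("segment must be 1-D with at least 8 samples")
    try:
        pywt.ContinuousWavelet(config.wavelet)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet {config.wavelet!r}") from exc
    scales, _ = scale_grid(config)
    coeffs, _ = pywt.cwt(
        segment, scales, config.wavelet, sampling_period=1.0 / config.fs
    )
    return np.abs(coeffs)


def bilinear_resize(matrix: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resampling with align-corners=false pixel-center semantics."""
    matrix = np.asarray(matrix, dtype=np.float64)
    in_h, in_w = matrix.shape

    def coords(n_out: int, n_in: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        x = np.clip(x, 0.0, n_in - 1.0)
        lo = np.floor(x).astype(int)
        hi = np.minimum(lo + 1, n_in - 1)
        return lo, hi, x - lo

    r0, r1, wr = coords(out_h, in_h)
    c0, c1, wc = coords(out_w, in_w)
    top = matrix[np.ix_(r0, c0)] * (1 - wc) + matrix[np.ix_(r0, c1)] * wc
    bot = matrix[np.ix_(r1, c0)] * (1 - wc) + matrix[np.ix_(r1, c1)] * wc
    return top * (1 - wr[:, None]) + bot * wr[:, None]


def to_image(
    matrix: np.ndarray, config: ScalogramConfig = ScalogramConfig()
) -> ScalogramImage:
    """Min-max normalize, resize, color-map.

    A constant matrix normalizes to all zeros (colormap entry 0).  Rows are
    flipped so the lowest scales (highest frequencies) end up at the bottom
    of the image, the usual scalogram orientation.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
    if matrix.size == 0:
        raise ValueError("empty coefficient matrix")
    lo, hi = matrix.min(), matrix.max()
    norm = (matrix - lo) / (hi - lo) if hi > lo else np.zeros_like(matrix)
    resized = bilinear_resize(norm, config.out_size, config.out_size)
    resized = np.clip(resized, 0.0, 1.0)[::-1]  # low scales at the bottom row
    lut = load_colormap(config.colormap)
    idx = np.round(resized * 255).astype(np.intp)
    return ScalogramImage(pixels=lut[idx].astype(np.float32), provenance=config)


def segment_to_image(
    segment: np.ndarray, config: ScalogramConfig = ScalogramConfig()
) -> ScalogramImage:
    """Full transform for one beat window."""
    return to_image(cwt_magnitude(segment, config), config)


def export_png(image: ScalogramImage, path: str) -> None:
    """Write the image as an 8-bit PNG for visual inspection (needs pillow)."""
    from PIL import Image

    arr = np.round(image.pixels * 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)
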