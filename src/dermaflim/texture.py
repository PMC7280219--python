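"""Frame-level structural texture features.

Two features summarise the spatial structure of a two-photon intensity
image without segmenting cells:

* **Fourier parameter** — the ratio of the mean Fourier magnitude in a
  high-spatial-frequency annulus to that in a medium-frequency annulus.
  Mitochondrial clusters appear as sharp, well-defined puncta and raise
  the high-frequency content, so inflamed skin yields larger ratios.  Low
  frequencies (including DC) carry illumination rather than cellular
  composition, and very high frequencies are noise-dominated; both are
  excluded by construction.
* **Mean local entropy** — the Shannon entropy (base 2) of the intensity
  histogram inside a small circular neighbourhood of each pixel, averaged
  over the frame.  Computing entropy locally before averaging suppresses
  the influence of slow illumination gradients.
"""

from __future__ import annotations

import numpy as np
from skimage.filters.rank import entropy as _rank_entropy
from skimage.morphology import disk

from .exceptions import ConfigurationError, DegenerateSpectrumError, ValidationError

__all__ = [
    "radial_annulus_average",
    "fourier_parameter",
    "local_entropy_image",
    "local_entropy_mean",
    "MEDIUM_ANNULUS_PX",
    "HIGH_ANNULUS_PX",
    "REFERENCE_FRAME_SIZE",
]

#: Annulus radii in FFT pixels, defined for a reference 512 px frame.
MEDIUM_ANNULUS_PX = (14.0, 24.0)
HIGH_ANNULUS_PX = (24.0, 36.0)
REFERENCE_FRAME_SIZE = 512


def _check_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.size == 0:
        raise ValidationError("frame must be a non-empty 2-D array")
    if not np.isfinite(frame).all():
        raise ValidationError("frame contains non-finite values")
    return frame


def radial_annulus_average(
    frame: np.ndarray, r_inner: float, r_outer: float
) -> float:
    """Mean |F| over the annulus ``r_inner <= d < r_outer`` of the 2-D DFT.

    The spectrum is centred (zero frequency at the array centre) and ``d``
    is the Euclidean distance from the centre in FFT pixels.  The inner
    radius is inclusive, the outer exclusive, so adjacent annuli sharing a
    boundary partition the plane without double counting.
    """
    frame = _check_frame(frame)
    h, w = frame.shape
    if not 0 < r_inner < r_outer:
        raise ConfigurationError("require 0 < r_inner < r_outer")
    if r_outer > min(h, w) / 2:
        raise ConfigurationError(
            f"outer radius {r_outer} exceeds the Nyquist box of a "
            f"{h}x{w} frame"
        )
    spectrum = np.abs(np.fft.fftshift(np.fft.fft2(frame)))
    cy, cx = h // 2, w // 2
    yy, xx = np.ogrid[:h, :w]
    d = np.hypot(yy - cy, xx - cx)
    mask = (d >= r_inner) & (d < r_outer)
    if not mask.any():
        raise ConfigurationError("annulus contains no FFT pixels")
    return float(spectrum[mask].mean())


def fourier_parameter(
    frame: np.ndarray,
    medium: tuple[float, float] = MEDIUM_ANNULUS_PX,
    high: tuple[float, float] = HIGH_ANNULUS_PX,
    scale_with_frame: bool = True,
    invert: bool = False,
) -> float:
    """High-to-medium spatial-frequency ratio of a frame.

    ``medium`` and ``high`` are annulus radii in FFT pixels for a
    :data:`REFERENCE_FRAME_SIZE` frame; with ``scale_with_frame=True``
    (default) they are rescaled proportionally to the actual frame size so
    the bands sit at the same fraction of the Nyquist frequency.  The
    result is invariant to adding a constant to the frame (DC is excluded
    by the annuli).  ``invert=True`` returns medium/high instead.
    """
    frame = _check_frame(frame)
    scale = min(frame.shape) / REFERENCE_FRAME_SIZE if scale_with_frame else 1.0
    med = (medium[0] * scale, medium[1] * scale)
    hi = (high[0] * scale, high[1] * scale)
    medium_avg = radial_annulus_average(frame, *med)
    high_avg = radial_annulus_average(frame, *hi)
    if medium_avg == 0:
        raise DegenerateSpectrumError(
            "medium-frequency annulus has zero mean magnitude"
        )
    ratio = high_avg / medium_avg
    if invert:
        if high_avg == 0:
            raise DegenerateSpectrumError(
                "high-frequency annulus has zero mean magnitude"
            )
        ratio = medium_avg / high_avg
    return float(ratio)


def quantize_frame(frame: np.ndarray, levels: int = 256) -> np.ndarray:
    """Min-max quantize a frame to ``levels`` gray levels (uint8/uint16)."""
    frame = _check_frame(frame)
    if levels < 2:
        raise ConfigurationError("levels must be >= 2")
    lo, hi = frame.min(), frame.max()
    if hi == lo:
        q = np.zeros(frame.shape, dtype=np.uint16)
    else:
        q = np.floor((frame - lo) / (hi - lo) * levels).astype(np.int64)
        q = np.clip(q, 0, levels - 1).astype(np.uint16)
    if levels <= 256:
        return q.astype(np.uint8)
    return q


def local_entropy_image(
    frame: np.ndarray, radius: int = 2, levels: int = 256
) -> np.ndarray:
    """Per-pixel local Shannon entropy (bits) of the quantized frame.

    The frame is min-max quantized to ``levels`` gray levels; each pixel's
    entropy is that of the gray-level histogram inside the disk of the
    given radius centred on it (13 pixels for radius 2), with
    neighbourhoods clipped at the frame edges.
    """
    frame = _check_frame(frame)
    if radius < 1:
        raise ConfigurationError("radius must be >= 1")
    q = quantize_frame(frame, levels)
    return _rank_entropy(q, disk(radius))


def local_entropy_mean(
    frame: np.ndarray, radius: int = 2, levels: int = 256
) -> float:
    """Frame-mean local Shannon entropy in bits.

    Mean of :func:`local_entropy_image` over all pixels.  A constant frame
    has zero entropy everywhere.
    """
    return float(local_entropy_image(frame, radius, levels).mean())
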