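"""Conditioning of raw fluorescence movies before any measurement.

Order of operations in the standard pipeline: polarity correction (voltage
dyes report depolarisation as a fluorescence *decrease*), 3x3 Gaussian
spatial filtering with renormalised truncation at mask and image borders,
morphological top-hat baseline correction along time, and tissue
segmentation.  No temporal smoothing is applied anywhere.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .containers import FluorescenceMovie, TissueMask, as_mask

#: 4-connectivity structuring element for connected-component labelling.
_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def gaussian_kernel(size: int = 3, sigma: float = 1.5) -> np.ndarray:
    """Sampled 2-D Gaussian kernel of odd ``size``, normalised to sum 1."""
    if size % 2 == 0 or size < 1:
        raise ValueError(f"kernel size must be odd and >= 1, got {size}")
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    half = size // 2
    dx = np.arange(-half, half + 1)
    xx, yy = np.meshgrid(dx, dx)
    k = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


def gaussian_spatial_filter(
    movie: FluorescenceMovie,
    size: int = 3,
    sigma: float = 1.5,
    mask: TissueMask | np.ndarray | None = None,
) -> FluorescenceMovie:
    """Convolve every frame with a normalised sampled Gaussian.

    At image borders and mask edges the kernel weights falling on
    unavailable pixels are dropped and the remaining weights renormalised
    to sum 1, so no intensity bleeds in from outside the tissue and
    spatially constant frames are preserved exactly.  Out-of-mask pixels
    are returned unchanged.
    """
    kernel = gaussian_kernel(size, sigma)
    flags = as_mask(mask, movie.frame_shape)
    w = flags.astype(float)
    num = ndimage.correlate(movie.data * w[None, :, :],
                            kernel[None, :, :], mode="constant", cval=0.0)
    den = ndimage.correlate(w, kernel, mode="constant", cval=0.0)
    out = movie.data.copy()
    inm = flags & (den > 0)
    out[:, inm] = num[:, inm] / den[inm]
    return movie.with_data(out)


def tophat_baseline(movie: FluorescenceMovie, kernel_ms: float) -> FluorescenceMovie:
    """Remove slow baseline drift by subtracting the grey-scale morphological
    opening (moving minimum then moving maximum) of each pixel trace.

    The flat structuring element spans ``round(kernel_ms * frame_rate/1000)``
    samples, forced odd (upward) so the opening is centred; it must be long
    relative to the action potential so depolarised plateaus are not eaten
    into the baseline.  A flat trace corrects to identically zero.  Apply
    only to upstroke-positive signals (after polarity handling).
    """
    if not kernel_ms > 0:
        raise ValueError("kernel_ms must be > 0")
    k = int(round(kernel_ms * movie.frame_rate / 1000.0))
    if k % 2 == 0:
        k += 1
    if k < 3:
        raise ValueError(
            f"top-hat kernel of {kernel_ms} ms is {k} sample(s) at "
            f"{movie.frame_rate} Hz; need at least 3"
        )
    baseline = ndimage.grey_opening(movie.data, size=(k, 1, 1), mode="nearest")
    return movie.with_data(movie.data - baseline)


def apply_polarity(movie: FluorescenceMovie) -> FluorescenceMovie:
    """Make depolarisation a positive deflection in every pixel trace.

    For ``inverted_voltage`` movies each pixel is replaced by its own
    maximum minus the trace (per-pixel reference, so resting-brightness
    gradients do not skew amplitudes); ``upright`` movies pass through.
    Idempotent once upright.
    """
    if movie.polarity == "upright":
        return movie
    ref = movie.data.max(axis=0, keepdims=True)
    return movie.with_data(ref - movie.data, polarity="upright")


def segment_tissue(
    movie: FluorescenceMovie,
    method: str = "amplitude_fraction",
    fraction: float = 0.3,
) -> TissueMask:
    """Segment analysable tissue pixels.

    ``amplitude_fraction`` includes a pixel iff its (max-min) signal
    amplitude is at least ``fraction`` times the 95th percentile of all
    pixel amplitudes.  Amplitudes are measured after a short temporal
    boxcar smooth (noise on dark pixels would otherwise inflate their
    max-min range); smoothing along time rather than space avoids
    bleeding signal across the tissue boundary into background pixels.
    ``otsu`` thresholds the time-averaged intensity image.  Only the
    largest 4-connected component is kept; holes are not filled.
    """
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames to segment tissue")
    if method == "amplitude_fraction":
        width = min(9, max(1, movie.n_frames // 3))
        smooth = ndimage.uniform_filter1d(movie.data, size=width, axis=0,
                                          mode="nearest")
        amp = smooth.max(axis=0) - smooth.min(axis=0)
        thr = fraction * np.percentile(amp, 95)
        flags = amp >= thr
    elif method == "otsu":
        from skimage.filters import threshold_otsu

        mean_img = movie.data.mean(axis=0)
        flags = mean_img > threshold_otsu(mean_img)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")

    if not flags.any():
        raise ValueError(
            "tissue segmentation produced an empty mask; try a lower "
            "amplitude fraction"
        )
    labels, n = ndimage.label(flags, structure=_FOUR_CONN)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        flags = labels == (1 + int(np.argmax(sizes)))
    return TissueMask(flags=flags)


def normalise_trace(trace: np.ndarray) -> np.ndarray:
    """Amplitude-normalise a 1-D trace to [0, 1] via (x - min)/(max - min)."""
    trace = np.asarray(trace, dtype=float)
    lo, hi = trace.min(), trace.max()
    if not hi > lo:
        raise ValueError("cannot normalise a flat trace (zero amplitude)")
    return (trace - lo) / (hi - lo)
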