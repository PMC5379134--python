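"""Patch extraction and the eight-feature representation.

Every candidate is described by the 11x11 window centered on it. Eight
per-window feature images are computed — raw intensity (F1), histogram
equalization (F2), Canny edges of the raw and of the equalized window
(F3, F4), grayscale morphological closing and opening (F5, F6), gradient
magnitude (F7), and a wavelet-denoised copy (F8). Each feature image is
flattened and l2-normalized into one column of a p x K feature stack
(p = 121, K = 8). All-zero columns (e.g. no edges in a flat window) are
left as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage
from skimage import exposure, feature, morphology
from skimage.filters import sobel

from .config import PipelineConfig
from .errors import ShapeError
from .preprocess import GrayImage

FEATURE_CODES = ("F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8")


@dataclass
class Patch:
    """A square window around a candidate center with its unit vector."""

    window: np.ndarray
    center: tuple[int, int]
    vector: np.ndarray


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64).ravel()
    nrm = np.linalg.norm(v)
    return v / nrm if nrm > 0 else v.copy()


def extract_patch(image: GrayImage | np.ndarray, center: tuple[int, int],
                  size: int = 11) -> Patch:
    """Window of ``size x size`` centered on ``center`` (row, col).

    Windows running off the image are completed by reflection padding.
    """
    values = image.values if isinstance(image, GrayImage) else np.asarray(image)
    r, c = int(center[0]), int(center[1])
    if not (0 <= r < values.shape[0] and 0 <= c < values.shape[1]):
        raise ShapeError(f"patch center {center} outside image {values.shape}")
    half = size // 2
    r0, r1 = r - half, r + half + 1
    c0, c1 = c - half, c + half + 1
    pr0, pr1 = max(0, -r0), max(0, r1 - values.shape[0])
    pc0, pc1 = max(0, -c0), max(0, c1 - values.shape[1])
    window = values[max(0, r0):min(values.shape[0], r1),
                    max(0, c0):min(values.shape[1], c1)]
    if pr0 or pr1 or pc0 or pc1:
        window = np.pad(window, ((pr0, pr1), (pc0, pc1)), mode="symmetric")
    window = np.asarray(window, dtype=np.float64)
    return Patch(window=window, center=(r, c), vector=_unit(window))


def _canny_edges(window: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Canny with hysteresis thresholds at 40%/80% of the gradient range."""
    grad = sobel(ndimage.gaussian_filter(window, sigma, mode="reflect"))
    gmax = float(grad.max())
    if gmax <= 0:
        return np.zeros_like(window)
    edges = feature.canny(window, sigma=sigma,
                          low_threshold=0.4 * gmax, high_threshold=0.8 * gmax)
    return edges.astype(np.float64)


def _hist_equalize(window: np.ndarray) -> np.ndarray:
    if np.ptp(window) == 0:
        return window.copy()
    return exposure.equalize_hist(window, nbins=256)


def _wavelet_denoise(window: np.ndarray, wavelet: str = "db2") -> np.ndarray:
    """Single-level soft-threshold denoising at the universal threshold."""
    approx, details = pywt.dwt2(window, wavelet, mode="symmetric")
    sigma = np.median(np.abs(details[2])) / 0.6745 if np.any(details[2]) else 0.0
    thr = sigma * np.sqrt(2.0 * np.log(window.size))
    shrunk = tuple(np.sign(d) * np.maximum(np.abs(d) - thr, 0.0) for d in details)
    rec = pywt.idwt2((approx, shrunk), wavelet, mode="symmetric")
    return rec[: window.shape[0], : window.shape[1]]


def compute_features(window: np.ndarray, n_features: int = 8) -> np.ndarray:
    """The p x K feature stack of one window, columns ordered F1..F8.

    ``n_features`` < 8 keeps the leading features only (K=1 reduces the
    representation to the plain grayscale patch).
    """
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 2 or window.shape[0] != window.shape[1]:
        raise ShapeError("window must be square")
    if not (1 <= n_features <= 8):
        raise ShapeError("n_features must be in 1..8")
    selem = morphology.disk(1)
    eq = _hist_equalize(window)
    feats = [
        window,                                   # F1 raw grayscale
        eq,                                       # F2 histogram equalized
        _canny_edges(window),                     # F3 Canny of raw
        _canny_edges(eq),                         # F4 Canny of equalized
        morphology.closing(window, selem),        # F5 morphological close
        morphology.opening(window, selem),        # F6 morphological open
        sobel(window),                            # F7 gradient magnitude
        _wavelet_denoise(window),                 # F8 wavelet denoised
    ][:n_features]
    return np.column_stack([_unit(f) for f in feats])


def feature_stack(image: GrayImage | np.ndarray, center: tuple[int, int],
                  config: PipelineConfig | None = None) -> np.ndarray:
    """Extract the patch at ``center`` and compute its feature stack."""
    config = config or PipelineConfig()
    patch = extract_patch(image, center, config.patch_size)
    return compute_features(patch.window, config.n_features)
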