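"""Preprocessing: green channel, field-of-view mask, contrast enhancement.

Microaneurysms have their best contrast against the background in the green
plane of a color fundus photograph, so all downstream analysis runs on the
green channel. The field of view (FOV) — the illuminated circular retina —
is segmented by Otsu thresholding followed by morphological cleanup; pixels
outside it carry no information and are zeroed. Contrast is equalized with
CLAHE and noise suppressed with a small Gaussian, then the image is brought
to a fixed square working resolution by bicubic interpolation.

Stage order is: green -> FOV -> CLAHE -> Gaussian smoothing -> resize.
The FOV mask is computed at the original resolution and resized with
nearest-neighbor interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, morphology, transform
from skimage.filters import threshold_otsu

from .config import PipelineConfig
from .errors import DegenerateInputError, ShapeError
from .io import FundusImage


@dataclass
class GrayImage:
    """A 2-D float intensity field in [0, 1] with an optional FOV mask."""

    values: np.ndarray
    fov: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ShapeError("GrayImage values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ShapeError("GrayImage values must be finite")
        if self.fov is not None:
            self.fov = np.asarray(self.fov, dtype=bool)
            if self.fov.shape != self.values.shape:
                raise ShapeError("FOV mask shape must match image shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def extract_green(image: FundusImage) -> GrayImage:
    """Green plane scaled to [0, 1]."""
    return GrayImage(values=image.pixels[:, :, 1].astype(np.float64) / 255.0)


def extract_fov(green: GrayImage, disk_radius: int = 2) -> np.ndarray:
    """Segment the circular field of view on the green channel.

    Coarse mask by Otsu thresholding, then morphological opening and closing
    with a disc structuring element (radius 2 by default), keeping the
    largest connected component. Raises :class:`DegenerateInputError` when
    no foreground survives (e.g. a constant image with no bimodality).
    """
    vals = green.values
    if np.ptp(vals) == 0:
        raise DegenerateInputError("constant image: Otsu threshold undefined")
    thr = threshold_otsu(vals)
    coarse = vals > thr
    selem = morphology.disk(disk_radius)
    cleaned = morphology.closing(morphology.opening(coarse, selem), selem)
    labels, n = ndimage.label(cleaned)
    if n == 0:
        raise DegenerateInputError("empty FOV mask after morphological cleanup")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def gaussian_smooth(values: np.ndarray, sigma: float = 1.0, width: int = 5) -> np.ndarray:
    """Gaussian blur with an explicit odd kernel support (width x width)."""
    radius = (width - 1) // 2
    return ndimage.gaussian_filter(values, sigma=sigma, radius=radius, mode="reflect")


def enhance(green: GrayImage, fov: np.ndarray,
            config: PipelineConfig | None = None) -> GrayImage:
    """CLAHE then Gaussian smoothing; pixels outside the FOV are zeroed."""
    config = config or PipelineConfig()
    if fov.shape != green.shape:
        raise ShapeError("FOV mask shape must match image shape")
    vals = green.values
    flat = (not fov.any()) or np.ptp(vals[fov]) == 0
    if flat:
        # flat field: CLAHE is an identity by decision (no histogram to spread)
        eq = vals.copy()
    else:
        tiles = max(1, config.clahe_tiles)
        kernel = (max(1, vals.shape[0] // tiles), max(1, vals.shape[1] // tiles))
        eq = exposure.equalize_adapthist(
            np.clip(vals, 0.0, 1.0), kernel_size=kernel,
            clip_limit=config.clahe_clip_limit,
        )
    sm = gaussian_smooth(eq, config.smoothing_sigma, config.smoothing_width)
    sm = np.clip(sm, 0.0, 1.0)
    sm[~fov] = 0.0
    return GrayImage(values=sm, fov=fov)


def resize_working(image: GrayImage, size: int | None = None,
                   config: PipelineConfig | None = None) -> GrayImage:
    """Resize to the square working resolution by bicubic interpolation.

    The FOV mask, when present, is resized with nearest-neighbor.
    """
    config = config or PipelineConfig()
    size = size or config.working_resolution
    if image.shape == (size, size):
        return GrayImage(values=image.values.copy(),
                         fov=None if image.fov is None else image.fov.copy())
    vals = transform.resize(image.values, (size, size), order=3,
                            mode="reflect", anti_aliasing=False)
    vals = np.clip(vals, 0.0, 1.0)
    fov = None
    if image.fov is not None:
        fov = transform.resize(image.fov.astype(float), (size, size), order=0,
                               mode="edge", anti_aliasing=False) > 0.5
    return GrayImage(values=vals, fov=fov)


def scale_coordinates(xy: np.ndarray, from_shape: tuple[int, int],
                      to_shape: tuple[int, int]) -> np.ndarray:
    """Rescale ``(x, y)`` coordinate pairs between image resolutions."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    sy = to_shape[0] / from_shape[0]
    sx = to_shape[1] / from_shape[1]
    out = np.empty_like(xy)
    out[:, 0] = xy[:, 0] * sx
    out[:, 1] = xy[:, 1] * sy
    return out


def preprocess_image(image: FundusImage,
                     config: PipelineConfig | None = None) -> GrayImage:
    """Full preprocessing chain to the enhanced working image with FOV."""
    config = config or PipelineConfig()
    green = extract_green(image)
    fov = extract_fov(green)
    enhanced = enhance(green, fov, config)
    return resize_working(enhanced, config.working_resolution, config)
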