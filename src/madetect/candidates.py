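"""Candidate extraction by multiscale Gaussian correlation filtering (MSCF).

A microaneurysm appears as a tiny dark blob whose intensity profile is close
to a 2-D Gaussian. At each pixel we compute the Pearson correlation between
a Gaussian template and the local window of the *inverted* working image
(1 - I), for five template scales sigma = 1.1 ... 1.5; inverting makes a dark
blob correlate positively, so the response lies in [0, 1] after clamping
negatives. The per-pixel maximum over scales is the final response map.

Candidates are pixels with response >= threshold (default 0.6), off the
vasculature and inside the FOV, grouped 8-connected. Each candidate's extent
is then refined by region growing from its darkest pixel with an adaptive
intensity threshold

    t = I_darkest - beta * (I_darkest - I_bg),       0 <= beta <= 1,

where I_bg is a mean-filtered background estimate at the seed. Regions larger
than 120 pixels are discarded (a microaneurysm is smaller than that at the
working resolution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .config import PipelineConfig
from .errors import ShapeError
from .preprocess import GrayImage

_EIGHT = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# correlation filtering


def gaussian_template(sigma: float, half: int | None = None) -> np.ndarray:
    """Square Gaussian matching template of half-width ceil(3*sigma)."""
    if half is None:
        half = math.ceil(3.0 * sigma)
    ax = np.arange(-half, half + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)
    return np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma ** 2))


def correlation_map(values: np.ndarray, sigma: float, half: int | None = None,
                    invert: bool = True) -> np.ndarray:
    """Per-pixel Pearson correlation with a Gaussian template at one scale.

    ``invert=True`` correlates against 1 - values so that dark blobs score
    positively. Negative coefficients are clamped to 0; windows with zero
    variance map to 0. Borders are handled by reflection.
    """
    values = np.asarray(values, dtype=np.float64)
    tmpl = gaussian_template(sigma, half)
    w = tmpl.shape[0]
    if values.ndim != 2 or values.shape[0] < w or values.shape[1] < w:
        raise ShapeError(f"image smaller than the {w}x{w} correlation window")
    y = 1.0 - values if invert else values
    n = float(w * w)
    xc = tmpl - tmpl.mean()
    sxx = float(np.sum(xc * xc))
    ones = np.ones_like(tmpl)
    # direct correlations (not FFT) keep summation exact enough for the
    # brute-force Pearson oracle to agree to ~1e-12
    num = ndimage.correlate(y, xc, mode="reflect")
    ysum = ndimage.correlate(y, ones, mode="reflect")
    ysq = ndimage.correlate(y * y, ones, mode="reflect")
    syy = ysq - ysum * ysum / n
    syy = np.maximum(syy, 0.0)
    denom = np.sqrt(sxx * syy)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 1e-12, num / denom, 0.0)
    return np.clip(r, 0.0, 1.0)


def multiscale_max(maps: list[np.ndarray]) -> np.ndarray:
    """Elementwise maximum across the single-scale response maps."""
    if not maps:
        raise ShapeError("no response maps given")
    shape = maps[0].shape
    for m in maps:
        if m.shape != shape:
            raise ShapeError("response maps have mismatched shapes")
    return np.maximum.reduce([np.asarray(m) for m in maps])


@dataclass
class ResponseMap:
    """Final MSCF response with (optionally) the per-scale maps retained."""

    values: np.ndarray
    per_scale: list[np.ndarray] | None = None
    sigmas: tuple[float, ...] | None = None


def multiscale_response(image: GrayImage, config: PipelineConfig | None = None,
                        keep_per_scale: bool = False) -> ResponseMap:
    """Run the Gaussian bank over the working image; zero outside the FOV."""
    config = config or PipelineConfig()
    per_scale = [correlation_map(image.values, s) for s in config.sigmas]
    final = multiscale_max(per_scale)
    if image.fov is not None:
        final = np.where(image.fov, final, 0.0)
    return ResponseMap(values=final,
                       per_scale=per_scale if keep_per_scale else None,
                       sigmas=config.sigmas)


# ---------------------------------------------------------------------------
# vessel exclusion


def vessel_mask(image: GrayImage, config: PipelineConfig | None = None,
                supplied: np.ndarray | None = None) -> np.ndarray:
    """Heuristic mask of the dark vasculature.

    Bottom-hat filtering with a disc larger than microaneurysm scale picks up
    all dark structures; components that are small or compact enough to be
    MA-like are then removed, leaving only elongated vessel segments. A
    user-supplied mask (from any external vessel segmentation) bypasses the
    heuristic entirely.
    """
    config = config or PipelineConfig()
    if supplied is not None:
        supplied = np.asarray(supplied, dtype=bool)
        if supplied.shape != image.shape:
            raise ShapeError("supplied vessel mask shape does not match image")
        return supplied
    selem = morphology.disk(config.vessel_bottomhat_radius)
    bh = morphology.black_tophat(image.values, selem)
    if image.fov is not None:
        bh = np.where(image.fov, bh, 0.0)
    binary = bh > config.vessel_threshold
    labels, n = ndimage.label(binary, structure=_EIGHT)
    if n == 0:
        return np.zeros(image.shape, dtype=bool)
    keep = np.zeros(n + 1, dtype=bool)
    for prop in measure.regionprops(labels):
        elongated = prop.eccentricity >= config.vessel_min_eccentricity
        large = prop.area > config.vessel_min_area
        if large and elongated:
            keep[prop.label] = True
    return keep[labels]


# ---------------------------------------------------------------------------
# thresholding, region growing, size filtering


@dataclass
class CandidateRegion:
    """A connected pixel set hypothesized to be a microaneurysm."""

    pixels: np.ndarray            # N x 2 array of (row, col)
    seed: tuple[int, int]         # darkest pixel, contained in `pixels`
    area: int
    score: float = 0.0            # peak MSCF response over the region
    image_id: str = ""
    oversized: bool = False       # growth escaped its bounding window

    @property
    def centroid(self) -> tuple[int, int]:
        rc = np.round(self.pixels.mean(axis=0)).astype(int)
        return int(rc[0]), int(rc[1])


def threshold_candidates(response: np.ndarray, threshold: float,
                         vessels: np.ndarray | None = None,
                         fov: np.ndarray | None = None) -> list[np.ndarray]:
    """8-connected seed components of {response >= threshold} off vessels.

    Returns one (N, 2) array of (row, col) pixel coordinates per component.
    """
    mask = np.asarray(response) >= threshold
    if fov is not None:
        mask &= fov
    if vessels is not None:
        mask &= ~vessels
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return []
    idx = np.argwhere(labels > 0)
    labs = labels[idx[:, 0], idx[:, 1]]
    order = np.argsort(labs, kind="stable")
    idx, labs = idx[order], labs[order]
    bounds = np.searchsorted(labs, np.arange(1, n + 2))
    return [idx[bounds[i]:bounds[i + 1]] for i in range(n)]


def adaptive_threshold(green: np.ndarray, component: np.ndarray,
                       config: PipelineConfig | None = None
                       ) -> tuple[float, tuple[int, int]]:
    """Adaptive growing threshold t = I_darkest - beta*(I_darkest - I_bg).

    ``I_darkest`` is the minimum intensity over the seed component dilated by
    a small margin; ``I_bg`` is the mean intensity in a background window
    centered on that darkest pixel. Returns ``(t, seed)``.
    """
    config = config or PipelineConfig()
    green = np.asarray(green, dtype=np.float64)
    comp = np.asarray(component)
    if comp.size == 0:
        raise ShapeError("empty seed component")
    pad = int(config.seed_dilation)
    r0 = max(0, comp[:, 0].min() - pad)
    r1 = min(green.shape[0], comp[:, 0].max() + pad + 1)
    c0 = max(0, comp[:, 1].min() - pad)
    c1 = min(green.shape[1], comp[:, 1].max() + pad + 1)
    local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    local[comp[:, 0] - r0, comp[:, 1] - c0] = True
    if pad > 0:
        local = ndimage.binary_dilation(local, structure=_EIGHT, iterations=pad)
    vals = green[r0:r1, c0:c1]
    masked = np.where(local, vals, np.inf)
    flat = int(np.argmin(masked))
    sr, sc = np.unravel_index(flat, masked.shape)
    seed = (int(sr + r0), int(sc + c0))
    i_darkest = float(masked[sr, sc])
    half_bg = config.bg_mean_window // 2
    br0 = max(0, seed[0] - half_bg)
    br1 = min(green.shape[0], seed[0] + half_bg + 1)
    bc0 = max(0, seed[1] - half_bg)
    bc1 = min(green.shape[1], seed[1] + half_bg + 1)
    i_bg = float(green[br0:br1, bc0:bc1].mean())
    t = i_darkest - config.beta * (i_darkest - i_bg)
    return t, seed


def region_grow(green: np.ndarray, seed: tuple[int, int], t: float,
                window_half: int = 40) -> CandidateRegion | None:
    """8-connected flood fill of pixels <= t from the seed.

    Growth is confined to a window of half-width ``window_half`` around the
    seed; a region touching the window edge (while not at the image border)
    is flagged oversized — it is far beyond any plausible microaneurysm and
    the size filter will discard it. Returns ``None`` when the seed itself is
    above the threshold (empty-region signal).
    """
    green = np.asarray(green, dtype=np.float64)
    sr, sc = seed
    if green[sr, sc] > t:
        return None
    r0 = max(0, sr - window_half)
    r1 = min(green.shape[0], sr + window_half + 1)
    c0 = max(0, sc - window_half)
    c1 = min(green.shape[1], sc + window_half + 1)
    crop = green[r0:r1, c0:c1]
    below = crop <= t
    labels, _ = ndimage.label(below, structure=_EIGHT)
    lab = labels[sr - r0, sc - c0]
    comp = np.argwhere(labels == lab)
    oversized = False
    edges = []
    if r0 > 0:
        edges.append(comp[:, 0] == 0)
    if r1 < green.shape[0]:
        edges.append(comp[:, 0] == crop.shape[0] - 1)
    if c0 > 0:
        edges.append(comp[:, 1] == 0)
    if c1 < green.shape[1]:
        edges.append(comp[:, 1] == crop.shape[1] - 1)
    if edges and np.any(np.concatenate(edges)):
        oversized = True
    pixels = comp + np.array([r0, c0])
    return CandidateRegion(pixels=pixels, seed=(sr, sc), area=len(pixels),
                           oversized=oversized)


def filter_by_size(regions: list[CandidateRegion],
                   max_area: int = 120) -> list[CandidateRegion]:
    """Discard regions larger than ``max_area`` pixels (kept at exactly 120)."""
    return [r for r in regions if not r.oversized and r.area <= max_area]


def extract_candidates(image: GrayImage, config: PipelineConfig | None = None,
                       vessels: np.ndarray | None = None,
                       threshold: float | None = None,
                       response: ResponseMap | None = None,
                       image_id: str = "",
                       apply_size_filter: bool = True
                       ) -> tuple[list[CandidateRegion], ResponseMap]:
    """Full candidate extraction for one preprocessed working image."""
    config = config or PipelineConfig()
    threshold = config.correlation_threshold if threshold is None else threshold
    if response is None:
        response = multiscale_response(image, config)
    if vessels is None:
        vessels = vessel_mask(image, config)
    comps = threshold_candidates(response.values, threshold, vessels, image.fov)
    regions: dict[tuple[int, int], CandidateRegion] = {}
    for comp in comps:
        t, seed = adaptive_threshold(image.values, comp, config)
        if seed in regions:       # two seed components sharing a darkest pixel
            continue
        region = region_grow(image.values, seed, t, config.grow_window_half)
        if region is None or region.area == 0:
            continue
        region.score = float(response.values[region.pixels[:, 0],
                                             region.pixels[:, 1]].max())
        region.image_id = image_id
        regions[seed] = region
    out = list(regions.values())
    if apply_size_filter:
        out = filter_by_size(out, config.max_region_area)
    return out, response
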