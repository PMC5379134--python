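"""Synthetic fundus scenes with known microaneurysm ground truth.

The generator emulates the image properties the detector relies on: a bright
circular field of view on a dark surround, a smooth low-frequency background,
dark curvilinear vessels (smoothed random walks — deliberately non-anatomical),
and microaneurysms implanted as small dark Gaussian blobs

    I(x) = background - contrast * exp(-|x - x0|^2 / (2 sigma^2)),

with sigma drawn from the same 1.1-1.5 range the matched filter bank covers.
Distractors exercise the failure modes: bright Gaussian spots (polarity) and
compact dark blobs larger than 120 px (size filter). Structure is dominant
in the green channel of the assembled RGB image. Everything is reproducible
from a single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import PipelineConfig
from .errors import MadetectError
from .fusion_dict import MA_CLASS, NON_MA_CLASS, LabeledTrainingSet
from .io import ANNOTATION_COLUMNS, FundusImage
from .patch_features import feature_stack
from .preprocess import preprocess_image

logger = logging.getLogger(__name__)


@dataclass
class SimulationParams:
    """Scene parameters; defaults describe a full-size working image."""

    image_size: int = 850
    fov_radius_frac: float = 0.46
    background_base: float = 0.55
    gradient_amplitude: float = 0.08
    n_vessels: int = 8
    vessel_width: tuple[float, float] = (2.0, 5.0)
    vessel_darkness: tuple[float, float] = (0.15, 0.30)
    n_ma: int = 10
    ma_sigma: tuple[float, float] = (1.1, 1.5)
    ma_contrast: tuple[float, float] = (0.15, 0.40)
    n_bright_distractors: int = 3
    n_large_distractors: int = 2
    large_distractor_radius: tuple[float, float] = (8.0, 11.0)
    noise_sd: float = 0.01
    min_separation: float = 22.0          # 2 x patch_size
    vessel_clearance: float = 10.0
    fov_margin: float = 15.0
    max_placement_tries: int = 20000
    seed: int = 0


@dataclass
class SyntheticScene:
    image: FundusImage
    green: np.ndarray                     # the float green-channel field
    vessel_mask: np.ndarray
    annotations: pd.DataFrame             # image_id, x, y
    distractors: list[dict] = field(default_factory=list)
    fov: np.ndarray | None = None
    params: SimulationParams | None = None


def _smooth_background(size: int, base: float, amplitude: float,
                       rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float) / size
    bg = np.full((size, size), base)
    for _ in range(2):
        theta = rng.uniform(0, 2 * np.pi)
        freq = rng.uniform(0.5, 1.5)
        phase = rng.uniform(0, 2 * np.pi)
        bg += (amplitude / 2.0) * np.sin(
            2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)) + phase
        )
    return bg


def _draw_vessels(size: int, fov: np.ndarray, params: SimulationParams,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Accumulated vessel darkness field and the boolean vessel mask."""
    darkness = np.zeros((size, size))
    mask = np.zeros((size, size), dtype=bool)
    center = size / 2.0
    R = params.fov_radius_frac * size
    for _ in range(params.n_vessels):
        width = rng.uniform(*params.vessel_width)
        depth = rng.uniform(*params.vessel_darkness)
        ang0 = rng.uniform(0, 2 * np.pi)
        r0 = rng.uniform(0.0, 0.5) * R
        pos = np.array([center + r0 * np.sin(ang0), center + r0 * np.cos(ang0)])
        heading = rng.uniform(0, 2 * np.pi)
        canvas = np.zeros((size, size), dtype=bool)
        for _ in range(int(2.2 * R)):
            heading += rng.normal(0.0, 0.10)
            pos = pos + np.array([np.sin(heading), np.cos(heading)])
            i, j = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= i < size and 0 <= j < size):
                break
            canvas[i, j] = True
        if not canvas.any():
            continue
        dist = ndimage.distance_transform_edt(~canvas)
        sigma_w = max(width / 2.0, 0.8)
        darkness = np.maximum(darkness, depth * np.exp(-(dist / sigma_w) ** 2 / 2.0))
        mask |= dist <= (width / 2.0 + 1.0)
    mask &= fov
    return darkness, mask


def _sample_point(rng: np.random.Generator, size: int, R: float,
                  margin: float) -> tuple[int, int]:
    center = size / 2.0
    rad = (R - margin) * np.sqrt(rng.uniform())
    ang = rng.uniform(0, 2 * np.pi)
    return (int(round(center + rad * np.sin(ang))),
            int(round(center + rad * np.cos(ang))))


def _place_points(n: int, rng: np.random.Generator, size: int, R: float,
                  margin: float, min_sep: float,
                  clearance_map: np.ndarray | None, clearance: float,
                  existing: list[tuple[int, int]],
                  max_tries: int) -> list[tuple[int, int]]:
    placed: list[tuple[int, int]] = []
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise MadetectError(
                f"could not place {n} points after {max_tries} tries; "
                "reduce n_MA or distractor counts"
            )
        tries += 1
        pt = _sample_point(rng, size, R, margin)
        if clearance_map is not None and clearance_map[pt] <= clearance:
            continue
        if any((pt[0] - q[0]) ** 2 + (pt[1] - q[1]) ** 2 < min_sep ** 2
               for q in placed + existing):
            continue
        placed.append(pt)
    return placed


def _stamp(field_arr: np.ndarray, center: tuple[int, int], profile_fn,
           half: int) -> None:
    size = field_arr.shape[0]
    r, c = center
    r0, r1 = max(0, r - half), min(size, r + half + 1)
    c0, c1 = max(0, c - half), min(size, c + half + 1)
    yy, xx = np.mgrid[r0 - r:r1 - r, c0 - c:c1 - c].astype(float)
    field_arr[r0:r1, c0:c1] += profile_fn(np.hypot(yy, xx))


def generate_scene(params: SimulationParams | None = None,
                   image_id: str | None = None) -> SyntheticScene:
    """Build one reproducible synthetic fundus scene."""
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    if image_id is None:
        image_id = f"sim{params.seed:05d}"
    center = size / 2.0
    R = params.fov_radius_frac * size
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    fov = np.hypot(yy - center, xx - center) <= R

    green = _smooth_background(size, params.background_base,
                               params.gradient_amplitude, rng)
    vessel_dark, vessel = _draw_vessels(size, fov, params, rng)
    green -= vessel_dark
    vessel_dist = ndimage.distance_transform_edt(~vessel)

    ma_centers = _place_points(
        params.n_ma, rng, size, R, params.fov_margin, params.min_separation,
        vessel_dist, params.vessel_clearance, [], params.max_placement_tries)
    ma_info = []
    for (r, c) in ma_centers:
        sigma = rng.uniform(*params.ma_sigma)
        contrast = rng.uniform(*params.ma_contrast)
        _stamp(green, (r, c),
               lambda d, s=sigma, k=contrast: -k * np.exp(-d ** 2 / (2 * s ** 2)),
               int(np.ceil(4 * sigma)))
        ma_info.append({"row": r, "col": c, "sigma": sigma, "contrast": contrast})

    distractors: list[dict] = []
    bright = _place_points(
        params.n_bright_distractors, rng, size, R, params.fov_margin,
        params.min_separation, vessel_dist, params.vessel_clearance,
        ma_centers, params.max_placement_tries)
    for (r, c) in bright:
        sigma = rng.uniform(2.0, 3.0)
        amp = rng.uniform(0.10, 0.25)
        _stamp(green, (r, c),
               lambda d, s=sigma, k=amp: k * np.exp(-d ** 2 / (2 * s ** 2)),
               int(np.ceil(4 * sigma)))
        distractors.append({"kind": "bright", "row": r, "col": c,
                            "sigma": sigma, "amplitude": amp})
    large = _place_points(
        params.n_large_distractors, rng, size, R, params.fov_margin + 10,
        max(params.min_separation, 30.0), vessel_dist,
        params.vessel_clearance, ma_centers + bright,
        params.max_placement_tries)
    for (r, c) in large:
        radius = rng.uniform(*params.large_distractor_radius)
        depth = rng.uniform(0.20, 0.35)
        # flat-topped super-Gaussian: dark core area ~ pi * radius^2 > 120 px
        _stamp(green, (r, c),
               lambda d, s=radius, k=depth: -k * np.exp(-(d / s) ** 4),
               int(np.ceil(2.2 * radius)))
        distractors.append({"kind": "large_dark", "row": r, "col": c,
                            "radius": radius, "depth": depth})

    green += rng.normal(0.0, params.noise_sd, green.shape)
    green = np.where(fov, green, 0.02)
    green = np.clip(green, 0.0, 1.0)

    smooth_bg = _smooth_background(size, params.background_base,
                                   params.gradient_amplitude,
                                   np.random.default_rng(params.seed + 1))
    red = np.where(fov, np.clip(0.75 * smooth_bg + 0.20 * green + 0.15, 0, 1), 0.03)
    blue = np.where(fov, np.clip(0.10 + 0.15 * green, 0, 1), 0.01)
    rgb = np.stack([red, green, blue], axis=-1)
    pixels = np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)

    annotations = pd.DataFrame(
        [(image_id, int(c), int(r)) for (r, c) in ma_centers],
        columns=ANNOTATION_COLUMNS,
    )
    return SyntheticScene(
        image=FundusImage(pixels=pixels, image_id=image_id),
        green=green, vessel_mask=vessel, annotations=annotations,
        distractors=distractors, fov=fov, params=params,
    )


def generate_scenes(params: SimulationParams, n_images: int
                    ) -> list[SyntheticScene]:
    """Independent scenes with per-image seeds derived from ``params.seed``."""
    scenes = []
    for i in range(n_images):
        p = replace(params, seed=params.seed + i)
        scenes.append(generate_scene(p, image_id=f"sim{params.seed:05d}_{i:03d}"))
    return scenes


def harvest_params(seed: int = 0, image_size: int = 850,
                   n_ma_per_scene: int = 60) -> SimulationParams:
    """Denser scenes used only to harvest patch training sets efficiently."""
    return SimulationParams(image_size=image_size, n_ma=n_ma_per_scene,
                            n_bright_distractors=6, n_large_distractors=3,
                            seed=seed)


def generate_patch_dataset(params: SimulationParams, n_per_class: int,
                           config: PipelineConfig | None = None
                           ) -> LabeledTrainingSet:
    """Balanced labeled feature stacks cut from synthetic scenes.

    MA patches are taken at implanted centers of the *preprocessed* working
    image; non-MA patches at distractor centers, at on-vessel points, and at
    random off-MA background locations.
    """
    if n_per_class < 1:
        raise MadetectError("n_per_class must be >= 1")
    config = config or PipelineConfig()
    stacks, labels, coords, ids = [], [], [], []
    n_ma = n_neg = 0
    scene_idx = 0
    while n_ma < n_per_class or n_neg < n_per_class:
        if scene_idx > 10 + 4 * (n_per_class // max(params.n_ma, 1)):
            raise MadetectError("insufficient valid patch locations")
        p = replace(params, seed=params.seed + scene_idx)
        scene = generate_scene(p, image_id=f"harvest{params.seed:05d}_{scene_idx:03d}")
        rng = np.random.default_rng(p.seed + 7919)
        working = preprocess_image(scene.image, config)
        factor = (working.shape[0] / scene.image.shape[0],
                  working.shape[1] / scene.image.shape[1])

        def to_working(rc):
            return (int(round(rc[0] * factor[0])), int(round(rc[1] * factor[1])))

        ma_pts = [(int(y), int(x)) for _, x, y in
                  scene.annotations[["image_id", "x", "y"]].itertuples(index=False)]
        for rc in ma_pts:
            if n_ma >= n_per_class:
                break
            wrc = to_working(rc)
            stacks.append(feature_stack(working, wrc, config))
            labels.append(MA_CLASS)
            coords.append(wrc)
            ids.append(scene.image.image_id)
            n_ma += 1

        neg_pts: list[tuple[int, int]] = [
            (d["row"], d["col"]) for d in scene.distractors]
        vessel_idx = np.argwhere(scene.vessel_mask)
        if len(vessel_idx):
            take = rng.choice(len(vessel_idx),
                              size=min(len(vessel_idx), params.n_ma // 2),
                              replace=False)
            neg_pts += [tuple(map(int, vessel_idx[i])) for i in take]
        n_bg = max(0, 2 * params.n_ma - len(neg_pts))
        R = params.fov_radius_frac * params.image_size
        bg_pts = _place_points(
            n_bg, rng, params.image_size, R, params.fov_margin,
            params.min_separation / 2.0, None, 0.0, ma_pts,
            params.max_placement_tries)
        # drop background points that landed near an MA
        ma_arr = np.asarray(ma_pts, dtype=float)
        for pt in bg_pts:
            if len(ma_arr) and np.min(np.linalg.norm(ma_arr - pt, axis=1)) < \
                    params.min_separation:
                continue
            neg_pts.append(pt)
        for rc in neg_pts:
            if n_neg >= n_per_class:
                break
            wrc = to_working(rc)
            stacks.append(feature_stack(working, wrc, config))
            labels.append(NON_MA_CLASS)
            coords.append(wrc)
            ids.append(scene.image.image_id)
            n_neg += 1
        scene_idx += 1
        logger.info("stage=harvest scene=%d ma=%d non_ma=%d",
                    scene_idx, n_ma, n_neg)
    return LabeledTrainingSet(
        stacks=np.asarray(stacks), labels=np.asarray(labels),
        coords=np.asarray(coords), image_ids=ids,
    )
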