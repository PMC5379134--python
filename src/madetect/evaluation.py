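"""Lesion-level scoring: sensitivity, FPPI, precision, and FROC curves.

Detections and ground-truth centers are matched one-to-one per image,
greedily by increasing Euclidean distance, with a match radius (default
5 px at the 850x850 working resolution). From the resulting counts:

    sensitivity = TP / (TP + FN)
    FPPI        = FP / number of images
    precision   = TP / (TP + FP)

An FROC curve collects (FPPI, sensitivity) operating points over a sweep of
the candidate threshold; sensitivities at the seven fixed FPPI readout
points (1, 2, 4, 8, 12, 16, 20) are obtained by linear interpolation
(clamped at the curve's endpoints) and averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MadetectError
from .io import MA_LABEL

FIXED_FPPI_POINTS = (1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 20.0)


@dataclass
class MatchResult:
    """One-to-one detection/ground-truth matching counts."""

    TP: int
    FP: int
    FN: int
    n_images: int
    pairs: list[tuple[tuple[str, int, int], tuple[str, int, int]]] = field(
        default_factory=list)


def _ma_only(dets: pd.DataFrame) -> pd.DataFrame:
    if "label" in dets.columns:
        return dets[dets["label"] == MA_LABEL]
    return dets


def match_detections(dets: pd.DataFrame, gt: pd.DataFrame, radius: float = 5.0,
                     n_images: int | None = None) -> MatchResult:
    """Greedy nearest-first one-to-one matching within ``radius`` pixels.

    Only detections labeled MA participate. ``n_images`` defaults to the
    number of distinct image ids across both tables (for FPPI, images with
    neither detections nor lesions must be counted explicitly by the caller).
    """
    if radius < 0:
        raise MadetectError("match radius must be nonnegative")
    dets = _ma_only(dets)
    ids = sorted(set(dets["image_id"].astype(str)) | set(gt["image_id"].astype(str)))
    if n_images is None:
        n_images = len(ids)
    tp = fp = fn = 0
    pairs = []
    for image_id in ids:
        d = dets[dets["image_id"].astype(str) == image_id]
        g = gt[gt["image_id"].astype(str) == image_id]
        dxy = d[["x", "y"]].to_numpy(dtype=float)
        gxy = g[["x", "y"]].to_numpy(dtype=float)
        if len(dxy) == 0 or len(gxy) == 0:
            fp += len(dxy)
            fn += len(gxy)
            continue
        dist = np.linalg.norm(dxy[:, None, :] - gxy[None, :, :], axis=2)
        free_d = np.ones(len(dxy), dtype=bool)
        free_g = np.ones(len(gxy), dtype=bool)
        while True:
            masked = np.where(np.outer(free_d, free_g), dist, np.inf)
            i, j = np.unravel_index(np.argmin(masked), masked.shape)
            if not np.isfinite(masked[i, j]) or masked[i, j] > radius:
                break
            free_d[i] = free_g[j] = False
            tp += 1
            pairs.append(((image_id, int(dxy[i, 0]), int(dxy[i, 1])),
                          (image_id, int(gxy[j, 0]), int(gxy[j, 1]))))
        fp += int(free_d.sum())
        fn += int(free_g.sum())
    return MatchResult(TP=tp, FP=fp, FN=fn, n_images=n_images, pairs=pairs)


def sensitivity(match: MatchResult) -> float:
    """TP / (TP + FN); 1.0 when there is neither truth nor detections."""
    if match.TP + match.FN == 0:
        return 0.0 if match.FP > 0 else 1.0
    return match.TP / (match.TP + match.FN)


def fppi(match: MatchResult) -> float:
    """False positives per image."""
    if match.n_images == 0:
        raise MadetectError("FPPI undefined for zero images")
    return match.FP / match.n_images


def precision(match: MatchResult) -> float:
    """TP / (TP + FP); NaN (with a warning) when nothing was detected."""
    if match.TP + match.FP == 0:
        warnings.warn("precision undefined: no detections")
        return float("nan")
    return match.TP / (match.TP + match.FP)


@dataclass
class FROCPoint:
    threshold: float
    sensitivity: float
    fppi: float


@dataclass
class FROCResult:
    points: list[FROCPoint]
    fixed_fppi: tuple[float, ...]
    fixed_sensitivity: np.ndarray
    average_sensitivity: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.threshold, p.sensitivity, p.fppi) for p in self.points],
            columns=["threshold", "sensitivity", "fppi"],
        )


def froc_curve(matches: dict[float, MatchResult] | list[tuple[float, MatchResult]],
               fixed_points: tuple[float, ...] = FIXED_FPPI_POINTS) -> FROCResult:
    """FROC curve from per-threshold match results plus the fixed-FPPI readout.

    Sensitivity at each fixed FPPI is linearly interpolated between
    bracketing measured points and clamped to the nearest endpoint outside
    the measured range; the average is the unweighted mean over the readout
    points.
    """
    items = sorted(matches.items()) if isinstance(matches, dict) else sorted(matches)
    if len(items) < 2:
        raise MadetectError("FROC needs at least two operating points")
    points = [FROCPoint(threshold=thr, sensitivity=sensitivity(m), fppi=fppi(m))
              for thr, m in items]
    order = np.argsort([p.fppi for p in points], kind="stable")
    xs = np.asarray([points[i].fppi for i in order])
    ys = np.asarray([points[i].sensitivity for i in order])
    fixed_sens = np.interp(np.asarray(fixed_points), xs, ys)
    return FROCResult(points=[points[i] for i in order],
                      fixed_fppi=tuple(fixed_points),
                      fixed_sensitivity=fixed_sens,
                      average_sensitivity=float(fixed_sens.mean()))


def froc_from_detections(dets: pd.DataFrame, gt: pd.DataFrame,
                         thresholds: np.ndarray | list[float],
                         radius: float = 5.0,
                         n_images: int | None = None) -> FROCResult:
    """Sweep the candidate-score threshold over a fixed detection table.

    The detections must have been produced at (or below) the smallest
    threshold in the sweep; each operating point keeps the MA-labeled
    detections with score >= threshold. Sensitivity is then non-decreasing
    as FPPI grows, by construction.
    """
    if n_images is None:
        ids = set(dets["image_id"].astype(str)) | set(gt["image_id"].astype(str))
        n_images = len(ids)
    matches = {}
    for thr in thresholds:
        kept = dets[dets["score"] >= thr]
        matches[float(thr)] = match_detections(kept, gt, radius, n_images)
    return froc_curve(matches)


def plot_froc(result: FROCResult, path) -> None:
    """Save an FROC plot (sensitivity vs FPPI) as an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    frame = result.as_frame().sort_values("fppi")
    ax.plot(frame["fppi"], frame["sensitivity"], "o-", color="tab:blue")
    ax.set_xlabel("false positives per image")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"FROC (avg sensitivity {result.average_sensitivity:.3f})")
    ax.grid(True, alpha=0.3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
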