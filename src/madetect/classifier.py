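"""Candidate classification by accumulated reconstruction error.

A query feature stack X (p x K) is projected to Y = X W (p x M). Each fused
channel y_m is OMP-coded against the class-c subdictionary Q_m^c and the
squared residuals are accumulated over channels:

    error_c = sum_m  min_beta || y_m - Q_m^c beta ||^2,   |beta|_0 <= T.

The query is assigned to the class with the smallest accumulated error; an
exact tie goes to the MA class to favor screening sensitivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .candidates import CandidateRegion, extract_candidates
from .config import PipelineConfig
from .errors import ModelMismatchError, ShapeError
from .fusion_dict import MA_CLASS, FusionDictionaryModel, fuse
from .io import DETECTION_COLUMNS, MA_LABEL, NON_MA_LABEL, FundusImage, empty_detections
from .patch_features import feature_stack
from .preprocess import GrayImage, preprocess_image
from .sparse import omp

logger = logging.getLogger(__name__)


@dataclass
class SparseCode:
    """OMP result: dense coefficients, support, and squared residual."""

    coefficients: np.ndarray
    support: np.ndarray
    residual: float


@dataclass
class ClassDecision:
    """Predicted class with per-class and per-channel reconstruction errors."""

    label: int
    per_class_error: dict[int, float]
    per_feature_errors: dict[int, np.ndarray]

    @classmethod
    def from_errors(cls, per_feature_errors: dict[int, np.ndarray],
                    tie_break: int = MA_CLASS) -> "ClassDecision":
        per_class = {c: float(np.sum(e)) for c, e in per_feature_errors.items()}
        best = min(per_class.values())
        winners = sorted(c for c, e in per_class.items() if e == best)
        label = tie_break if tie_break in winners else winners[0]
        return cls(label=label, per_class_error=per_class,
                   per_feature_errors=per_feature_errors)


def sparse_code(y: np.ndarray, dictionary: np.ndarray, sparsity: int) -> SparseCode:
    """OMP-code a fused channel against one subdictionary."""
    if sparsity < 1:
        raise ShapeError("sparsity must be >= 1")
    beta, support, residual = omp(dictionary, y, sparsity)
    return SparseCode(coefficients=beta, support=support, residual=residual)


def classify(X: np.ndarray, model: FusionDictionaryModel,
             sparsity: int | None = None) -> ClassDecision:
    """Label one feature stack with the trained model."""
    sparsity = sparsity or model.config.omp_sparsity
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != model.fusion.W.shape[0]:
        raise ShapeError(
            f"stack has K={X.shape[1]} features, model expects "
            f"{model.fusion.W.shape[0]}"
        )
    Y = fuse(X, model.fusion)
    errors: dict[int, np.ndarray] = {}
    for c in model.classes:
        per_m = np.empty(model.fused_dim)
        for m in range(model.fused_dim):
            per_m[m] = sparse_code(Y[:, m], model.subdictionaries[(m, c)],
                                   sparsity).residual
        errors[c] = per_m
    return ClassDecision.from_errors(errors, model.config.tie_break_label)


def _check_compatible(model: FusionDictionaryModel, config: PipelineConfig) -> None:
    mismatches = [
        name for name in ("patch_size", "n_features", "fused_dim")
        if getattr(model.config, name) != getattr(config, name)
    ]
    if mismatches:
        raise ModelMismatchError(
            "model/config mismatch in fields: " + ", ".join(mismatches)
        )


def detect_in_working_image(working: GrayImage, model: FusionDictionaryModel,
                            config: PipelineConfig | None = None,
                            vessels: np.ndarray | None = None,
                            image_id: str = "",
                            threshold: float | None = None) -> pd.DataFrame:
    """Candidate extraction + classification on a preprocessed image.

    Returns a detection table with every surviving candidate and its
    predicted label; the score column carries the candidate's peak MSCF
    response (the FROC ranking score).
    """
    config = config or model.config
    _check_compatible(model, config)
    regions, _ = extract_candidates(working, config, vessels=vessels,
                                    threshold=threshold, image_id=image_id)
    return classify_regions(working, regions, model, config, image_id)


def classify_regions(working: GrayImage, regions: list[CandidateRegion],
                     model: FusionDictionaryModel,
                     config: PipelineConfig | None = None,
                     image_id: str = "") -> pd.DataFrame:
    """Classify candidate regions; one detection row per region."""
    config = config or model.config
    rows = []
    for region in regions:
        r, c = region.centroid
        X = feature_stack(working, (r, c), config)
        decision = classify(X, model)
        rows.append((image_id or region.image_id, c, r, region.score,
                     MA_LABEL if decision.label == MA_CLASS else NON_MA_LABEL))
    if not rows:
        return empty_detections()
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def detect(image: FundusImage, model: FusionDictionaryModel,
           config: PipelineConfig | None = None,
           vessels: np.ndarray | None = None,
           threshold: float | None = None) -> pd.DataFrame:
    """Full pipeline on a raw fundus photograph.

    Coordinates in the returned table are at the working resolution.
    A user-supplied vessel mask must match the *original* image shape; it is
    resized along with the image.
    """
    config = config or model.config
    _check_compatible(model, config)
    working = preprocess_image(image, config)
    if vessels is not None:
        from skimage import transform

        if vessels.shape != image.shape:
            raise ShapeError("vessel mask shape does not match image")
        vessels = transform.resize(
            vessels.astype(float), working.shape, order=0,
            mode="edge", anti_aliasing=False) > 0.5
    logger.info("stage=detect image=%s shape=%s", image.image_id, working.shape)
    return detect_in_working_image(working, model, config, vessels,
                                   image.image_id, threshold)
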