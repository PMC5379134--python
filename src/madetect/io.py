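"""File formats: fundus images, annotation/detection tables, model archives.

Coordinate convention (used everywhere in the package): pixel-centered,
0-based, ``(row=y, col=x)`` in arrays; CSV tables store ``x,y`` in
column,row order. Annotation CSVs have header ``image_id,x,y``; detection
CSVs have header ``image_id,x,y,score,label``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .config import PipelineConfig
from .errors import AnnotationParseError, ChannelError, MadetectError

ANNOTATION_COLUMNS = ["image_id", "x", "y"]
DETECTION_COLUMNS = ["image_id", "x", "y", "score", "label"]
MA_LABEL = "MA"
NON_MA_LABEL = "non-MA"


@dataclass
class FundusImage:
    """An 8-bit RGB fundus photograph."""

    pixels: np.ndarray  # H x W x 3 uint8
    image_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ChannelError(
                f"image '{self.image_id}' must have three channels, "
                f"got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 64 or self.pixels.shape[1] < 64:
            raise MadetectError(f"image '{self.image_id}' smaller than 64x64")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


def read_image(path: str | Path) -> FundusImage:
    """Read a PNG/JPEG/TIFF fundus photograph as 8-bit RGB."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode not in ("RGB", "RGBA"):
                if im.mode in ("L", "I", "I;16", "P", "1", "F"):
                    raise ChannelError(
                        f"'{path}' is not an RGB image (mode={im.mode}); "
                        "three channels are required"
                    )
                raise ChannelError(f"'{path}' has unsupported mode {im.mode}")
            arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except FileNotFoundError:
        raise
    except (ChannelError, MadetectError):
        raise
    except Exception as exc:  # pragma: no cover - decoder specific
        raise OSError(f"cannot decode image '{path}': {exc}") from exc
    return FundusImage(pixels=arr, image_id=path.stem)


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write an 8-bit grayscale or RGB raster (debug maps, simulations)."""
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(Path(path))


def _parse_int(value: str, name: str, line: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise AnnotationParseError(f"non-integer {name} value {value!r}", line)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a ground-truth table ``image_id,x,y`` (one MA center per row)."""
    rows = []
    header_seen = False
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].lstrip().startswith("#"):
                continue
            if not header_seen:
                if [c.strip() for c in row[:3]] != ANNOTATION_COLUMNS:
                    raise AnnotationParseError(
                        f"expected header {','.join(ANNOTATION_COLUMNS)}, got {row}", lineno
                    )
                header_seen = True
                continue
            if len(row) < 3:
                raise AnnotationParseError(f"expected 3 fields, got {len(row)}", lineno)
            rows.append(
                (
                    row[0].strip(),
                    _parse_int(row[1].strip(), "x", lineno),
                    _parse_int(row[2].strip(), "y", lineno),
                )
            )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).astype(
        {"image_id": str, "x": int, "y": int}
    )


def write_annotations(path: str | Path, table: pd.DataFrame) -> None:
    table = table[ANNOTATION_COLUMNS]
    with open(path, "w", newline="") as fh:
        fh.write("# x = column, y = row; 0-based pixel-centered coordinates\n")
        table.to_csv(fh, index=False)


def read_detections(path: str | Path) -> pd.DataFrame:
    """Read a detection table ``image_id,x,y,score,label``."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationParseError(f"detection table missing columns {missing}")
    return df[DETECTION_COLUMNS].astype(
        {"image_id": str, "x": int, "y": int, "score": float, "label": str}
    )


def write_detections(path: str | Path, table: pd.DataFrame) -> None:
    table = pd.DataFrame(table, columns=DETECTION_COLUMNS)
    with open(path, "w", newline="") as fh:
        fh.write("# x = column, y = row; 0-based pixel-centered coordinates\n")
        # %.17g guarantees scores survive the round-trip bit-exactly
        table.to_csv(fh, index=False, float_format="%.17g")


def empty_detections() -> pd.DataFrame:
    return pd.DataFrame(columns=DETECTION_COLUMNS)


# ---------------------------------------------------------------------------
# model archive


def save_model(model, path: str | Path) -> None:
    """Persist a trained model: fusion matrix, subdictionaries, config.

    The archive is a directory holding ``model.npz`` (W, eigenvalues, one
    array per class/feature subdictionary) and ``config.json``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {"W": model.fusion.W, "eigenvalues": model.fusion.eigenvalues}
    for (m, c), Q in model.subdictionaries.items():
        arrays[f"Q_m{m}_c{c}"] = Q
    np.savez(path / "model.npz", **arrays)
    model.config.to_json(path / "config.json")
    meta = {"classes": sorted({c for (_, c) in model.subdictionaries}),
            "fused_dim": model.fusion.W.shape[1]}
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path):
    """Load a model archive written by :func:`save_model`."""
    from .fusion_dict import FusionDictionaryModel, FusionMatrix

    path = Path(path)
    npz = np.load(path / "model.npz")
    config = PipelineConfig.from_json(path / "config.json")
    fusion = FusionMatrix(W=npz["W"], eigenvalues=npz["eigenvalues"])
    subs = {}
    for key in npz.files:
        if key.startswith("Q_m"):
            m_part, c_part = key[2:].split("_")
            subs[(int(m_part[1:]), int(c_part[1:]))] = npz[key]
    return FusionDictionaryModel(fusion=fusion, subdictionaries=subs, config=config)
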