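"""Reading and validating label-coded epidermal tracings.

The input format is a traced micrograph in which cell walls, pavement
cell interiors, stomata, subsidiary cells (and any extra cell types,
e.g. glands) each carry one distinct 8-bit value.  An optional NA value
marks regions excluded from measurement (damage, blur, incomplete field
of view).  This module turns such rasters into a validated
:class:`LabelMap` carrying the value-to-class mapping and scale
metadata; everything downstream works from class names, never raw
palette values, so different labs' colour conventions interoperate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "ValueConfig",
    "LabelMap",
    "LabelMapError",
    "UnknownValueError",
    "load_labelmap",
    "save_labelmap",
]

WALL = "wall"
NA = "na"


class LabelMapError(ValueError):
    """Invalid label map or value configuration."""


class UnknownValueError(LabelMapError):
    """Pixel values present in the image but absent from the config."""

    def __init__(self, counts: dict[int, int]):
        self.counts = dict(counts)
        detail = ", ".join(f"{v} ({n} px)" for v, n in sorted(counts.items()))
        super().__init__(
            f"image contains pixel values not present in the value config: {detail}. "
            "Anti-aliased tracings (intermediate grey values) are rejected; "
            "re-export the tracing with hard value boundaries."
        )


@dataclass(frozen=True)
class ValueConfig:
    """Mapping from raster values to cell classes, plus scale metadata.

    Parameters
    ----------
    wall_value : int
        Code of the cell-wall tracing, 0-255.
    class_values : dict
        Cell-class name -> code.  Standard names are ``"pavement"``,
        ``"stomate"``, ``"subsidiary"``; arbitrary extra classes
        (e.g. ``"gland"``) are allowed.
    na_value : int, optional
        Code marking not-to-be-measured regions.
    scale : float, optional
        Length units per pixel.  When absent, all scale-dependent
        measurements are reported in pixels.
    scale_units : str
        Unit label for ``scale`` (default micrometres).
    """

    wall_value: int
    class_values: dict[str, int] = field(default_factory=dict)
    na_value: int | None = None
    scale: float | None = None
    scale_units: str = "um"

    def __post_init__(self):
        codes = [self.wall_value, *self.class_values.values()]
        if self.na_value is not None:
            codes.append(self.na_value)
        if len(set(codes)) != len(codes):
            raise LabelMapError(f"value codes must be distinct, got {codes}")
        for c in codes:
            if not (0 <= int(c) <= 255):
                raise LabelMapError(f"value code {c} outside [0, 255]")
        if WALL in self.class_values or NA in self.class_values:
            raise LabelMapError(f"class names {WALL!r}/{NA!r} are reserved")
        if self.scale is not None and not self.scale > 0:
            raise LabelMapError(f"scale must be positive, got {self.scale}")

    @property
    def code_to_class(self) -> dict[int, str]:
        m = {int(self.wall_value): WALL}
        for name, code in self.class_values.items():
            m[int(code)] = name
        if self.na_value is not None:
            m[int(self.na_value)] = NA
        return m

    @classmethod
    def from_file(cls, path: str | Path) -> "ValueConfig":
        """Load a config from a JSON or YAML document."""
        path = Path(path)
        text = path.read_text()
        doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls(
            wall_value=int(doc["wall_value"]),
            class_values={str(k): int(v) for k, v in doc.get("class_values", {}).items()},
            na_value=None if doc.get("na_value") is None else int(doc["na_value"]),
            scale=None if doc.get("scale") is None else float(doc["scale"]),
            scale_units=str(doc.get("scale_units", "um")),
        )


@dataclass
class LabelMap:
    """Validated single-channel label raster with class mapping.

    ``grid`` is a 2-D uint8 array of raw codes, rows = y down, cols = x
    right, origin top-left.  ``measured_area`` is the area of non-NA
    pixels in scaled units (px^2 when no scale is set).
    """

    grid: np.ndarray
    config: ValueConfig

    def __post_init__(self):
        grid = np.asarray(self.grid)
        if grid.ndim != 2 or grid.shape[0] < 3 or grid.shape[1] < 3:
            raise LabelMapError(f"grid must be 2-D and at least 3x3, got shape {grid.shape}")
        self.grid = grid.astype(np.uint8, copy=False)
        known = np.array(sorted(self.config.code_to_class), dtype=np.uint8)
        present = np.unique(self.grid)
        unknown = np.setdiff1d(present, known)
        if unknown.size:
            counts = {int(v): int(np.count_nonzero(self.grid == v)) for v in unknown}
            raise UnknownValueError(counts)
        if self.config.scale is None:
            logger.warning(
                "no scale set: all scale-dependent measurements will be in pixels"
            )

    @property
    def scale(self) -> float:
        """Length units per pixel (1.0 when unscaled)."""
        return self.config.scale if self.config.scale is not None else 1.0

    @property
    def units(self) -> str:
        return self.config.scale_units if self.config.scale is not None else "px"

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def na_mask(self) -> np.ndarray:
        """Boolean mask of NA (excluded) pixels."""
        if self.config.na_value is None:
            return np.zeros(self.grid.shape, dtype=bool)
        return self.grid == self.config.na_value

    @property
    def class_grid(self) -> np.ndarray:
        """Object array of class names (``'wall'``/``'na'``/class names)."""
        lut = np.empty(256, dtype=object)
        for code, name in self.config.code_to_class.items():
            lut[code] = name
        return lut[self.grid]

    @property
    def measured_area(self) -> float:
        n = int(self.grid.size - np.count_nonzero(self.na_mask))
        return n * self.scale**2


def _read_raster(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        with Image.open(path) as im:
            arr = np.asarray(im)
    if arr.size == 0:
        raise OSError(f"empty image: {path}")
    return arr


def _collapse_channels(arr: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) raster to one channel iff channels agree."""
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3:
        raise LabelMapError(f"unsupported raster dimensionality: {arr.shape}")
    rgb = arr[..., :3]  # a fully opaque alpha channel is ignored
    if arr.shape[-1] == 4 and not np.all(arr[..., 3] == arr[..., 3].flat[0]):
        raise LabelMapError("alpha channel varies; cannot collapse to labels")
    if not np.all(rgb == rgb[..., :1]):
        bad = int(np.count_nonzero(np.any(rgb != rgb[..., :1], axis=-1)))
        raise LabelMapError(
            f"RGB channels disagree on {bad} pixels; image is not a label map"
        )
    return rgb[..., 0]


def load_labelmap(path: str | Path, config: ValueConfig) -> LabelMap:
    """Read a PNG/TIFF tracing and validate it against ``config``.

    Multi-channel images are collapsed to a single channel only when
    all channels are identical per pixel.  Every pixel value must match
    a config entry; unknown values raise :class:`UnknownValueError`
    listing the offending values and their counts.
    """
    arr = _collapse_channels(_read_raster(path))
    if not np.issubdtype(arr.dtype, np.integer):
        raise LabelMapError(f"expected integer raster, got dtype {arr.dtype}")
    if arr.min() < 0 or arr.max() > 255:
        raise LabelMapError("raster values outside [0, 255]")
    return LabelMap(grid=arr.astype(np.uint8), config=config)


def save_labelmap(labelmap: LabelMap, path: str | Path) -> None:
    """Re-export a canonical label map as single-channel PNG/TIFF."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, labelmap.grid)
    else:
        Image.fromarray(labelmap.grid, mode="L").save(path)
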