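"""Per-tile ROI determination and signal extraction.

Each mosaic tile carries three registered grayscale channels: DAPI (nuclei),
CK (pan-epithelial cytokeratin) and HER2 (membrane marker).  The region of
interest is the CK-positive (epithelial) area with the dilated DAPI-positive
(nuclear) area removed, since the membrane markers are not expressed in
nuclei.  Each tile then contributes one arithmetic-mean CK and HER2 signal
over its ROI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk

from .config import QuantConfig

__all__ = [
    "TileImage",
    "RoiMask",
    "TileMeasurement",
    "auto_threshold",
    "compute_roi",
    "measure_tile",
    "measure_case",
]

logger = logging.getLogger(__name__)


def _validate_channel(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 2-D array")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(f"{name} intensities must lie within [0, 1]")
    return arr


@dataclass(frozen=True)
class TileImage:
    """Registered DAPI/CK/HER2 intensity arrays for one mosaic tile.

    Intensities are normalized to [0, 1]; the tile grid is row-major and
    0-based.
    """

    dapi: np.ndarray
    ck: np.ndarray
    her2: np.ndarray
    tile_id: tuple[int, int]  # (row, col)

    def __post_init__(self) -> None:
        dapi = _validate_channel(self.dapi, "dapi")
        ck = _validate_channel(self.ck, "ck")
        her2 = _validate_channel(self.her2, "her2")
        if not (dapi.shape == ck.shape == her2.shape):
            raise ValueError("all three channels must share identical dimensions")
        object.__setattr__(self, "dapi", dapi)
        object.__setattr__(self, "ck", ck)
        object.__setattr__(self, "her2", her2)
        object.__setattr__(self, "tile_id", (int(self.tile_id[0]), int(self.tile_id[1])))

    @property
    def shape(self) -> tuple[int, int]:
        return self.ck.shape


@dataclass(frozen=True)
class RoiMask:
    """Epithelial, non-nuclear region of interest for one tile."""

    mask: np.ndarray  # boolean
    ck_threshold: float
    dapi_threshold: float

    @property
    def roi_area(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class TileMeasurement:
    """One tile's ROI-averaged CK and HER2 signals plus QC fields."""

    tile_id: tuple[int, int]
    ck_mean: float
    her2_mean: float
    roi_area: int
    valid: bool


def auto_threshold(channel: np.ndarray) -> float:
    """Intensity threshold maximizing between-class variance (Otsu criterion).

    For a constant array the constant itself is returned; callers treat the
    foreground of such a degenerate tile as empty.
    """
    arr = _validate_finite(channel)
    if np.ptp(arr) == 0:
        return float(arr.flat[0])
    return float(threshold_otsu(arr, nbins=256))


def _class_contrast(channel: np.ndarray, foreground: np.ndarray) -> float:
    """Mean intensity gap between the thresholded classes (0 if one is empty)."""
    n_fg = int(foreground.sum())
    if n_fg == 0 or n_fg == foreground.size:
        return 0.0
    return float(channel[foreground].mean() - channel[~foreground].mean())


def _validate_finite(channel: np.ndarray) -> np.ndarray:
    arr = np.asarray(channel, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot threshold an empty array")
    if not np.all(np.isfinite(arr)):
        raise ValueError("array contains non-finite values")
    return arr


def compute_roi(tile: TileImage, config: QuantConfig | None = None) -> RoiMask:
    """Epithelial (CK-positive) mask minus the dilated nuclear (DAPI) mask.

    Degenerate-tile guards: if the CK channel is constant, the mean contrast
    between its Otsu foreground and background classes falls below
    ``config.noise_floor``, or the CK foreground covers less than
    ``config.min_foreground_fraction`` of the tile, the ROI is empty —
    otherwise Otsu hallucinates foreground in stroma-only tiles, where the
    two classes are just halves of the noise distribution.  The same contrast
    floor disables nuclear exclusion on tiles without genuine DAPI signal.
    """
    config = config or QuantConfig()
    ck_t = auto_threshold(tile.ck)
    dapi_t = auto_threshold(tile.dapi)
    foreground = tile.ck >= ck_t
    degenerate = (
        np.ptp(tile.ck) == 0
        or _class_contrast(tile.ck, foreground) < config.noise_floor
        or foreground.mean() < config.min_foreground_fraction
    )
    if degenerate:
        mask = np.zeros(tile.shape, dtype=bool)
        return RoiMask(mask=mask, ck_threshold=ck_t, dapi_threshold=dapi_t)
    dapi_fg = tile.dapi >= dapi_t
    if np.ptp(tile.dapi) == 0 or _class_contrast(tile.dapi, dapi_fg) < config.noise_floor:
        nuclei = np.zeros(tile.shape, dtype=bool)
    else:
        nuclei = dapi_fg
        if config.dilation_radius > 0:
            nuclei = dilation(nuclei, disk(config.dilation_radius))
    mask = foreground & ~nuclei
    return RoiMask(mask=mask, ck_threshold=ck_t, dapi_threshold=dapi_t)


def measure_tile(
    tile: TileImage, roi: RoiMask, config: QuantConfig | None = None
) -> TileMeasurement:
    """Arithmetic-mean CK and HER2 over the ROI pixels of one tile."""
    config = config or QuantConfig()
    if roi.mask.shape != tile.shape:
        raise ValueError("ROI mask shape does not match the tile")
    area = roi.roi_area
    if area > 0:
        ck_mean = float(tile.ck[roi.mask].mean())
        her2_mean = float(tile.her2[roi.mask].mean())
    else:
        ck_mean = float("nan")
        her2_mean = float("nan")
    valid = area >= config.min_roi_pixels
    return TileMeasurement(
        tile_id=tile.tile_id,
        ck_mean=ck_mean,
        her2_mean=her2_mean,
        roi_area=area,
        valid=valid,
    )


def measure_case(
    tiles: Sequence[TileImage], config: QuantConfig | None = None
) -> list[TileMeasurement]:
    """One :class:`TileMeasurement` per tile, order preserved."""
    if len(tiles) == 0:
        raise ValueError("measure_case requires at least one tile")
    config = config or QuantConfig()
    measurements = [measure_tile(t, compute_roi(t, config), config) for t in tiles]
    n_invalid = sum(not m.valid for m in measurements)
    if n_invalid:
        logger.info("measure_case: %d/%d tiles invalid (ROI below %d px)",
                    n_invalid, len(measurements), config.min_roi_pixels)
    return measurements
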