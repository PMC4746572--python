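"""File formats: per-channel tile TIFFs, cohort/measurement/score CSVs.

Layout written and read per case::

    case_<id>/tile_<row>_<col>_<channel>.tif     # 16-bit grayscale

with ``channel`` one of ``dapi``, ``ck``, ``her2``.  Intensities are
normalized to [0, 1] on read by dividing by the dtype maximum.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .cohort import CohortRecord
from .quantify import TileImage, TileMeasurement

__all__ = [
    "CHANNELS",
    "write_case_images",
    "read_case_images",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_measurements_csv",
    "read_measurements_csv",
]

CHANNELS = ("dapi", "ck", "her2")
_TILE_RE = re.compile(r"^tile_(\d+)_(\d+)_(dapi|ck|her2)\.tif$")


def write_case_images(tiles: Sequence[TileImage], directory: str | Path) -> None:
    """Write one 16-bit grayscale TIFF per channel per tile."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for tile in tiles:
        row, col = tile.tile_id
        for channel in CHANNELS:
            arr = getattr(tile, channel)
            data = np.round(arr * np.iinfo(np.uint16).max).astype(np.uint16)
            tifffile.imwrite(directory / f"tile_{row:03d}_{col:03d}_{channel}.tif", data)


def read_case_images(path: str | Path) -> list[TileImage]:
    """Read a case directory into tiles sorted by (row, col).

    8- and 16-bit grayscale TIFFs are normalized to [0, 1] by the dtype
    maximum.  A tile missing any channel is a hard error naming the tile.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"case directory not found: {path}")
    found: dict[tuple[int, int], dict[str, Path]] = {}
    for f in path.iterdir():
        m = _TILE_RE.match(f.name)
        if m:
            tile_id = (int(m.group(1)), int(m.group(2)))
            found.setdefault(tile_id, {})[m.group(3)] = f
    if not found:
        raise FileNotFoundError(f"no tile TIFFs found in {path}")
    tiles = []
    for tile_id in sorted(found):
        channels = found[tile_id]
        missing = [c for c in CHANNELS if c not in channels]
        if missing:
            raise FileNotFoundError(
                f"tile {tile_id} is missing channel(s) {missing} in {path}"
            )
        arrays = {}
        for channel in CHANNELS:
            raw = tifffile.imread(channels[channel])
            if raw.dtype not in (np.uint8, np.uint16):
                raise ValueError(
                    f"tile {tile_id} channel {channel}: expected 8/16-bit, got {raw.dtype}"
                )
            arrays[channel] = raw.astype(float) / np.iinfo(raw.dtype).max
        tiles.append(TileImage(tile_id=tile_id, **arrays))
    return tiles


def write_cohort_csv(records: Iterable[CohortRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "case_id": r.case_id,
            "batch_id": r.batch_id,
            "role": r.role,
            "nfish_true": r.n_fish,
            "her2_cep17": r.her2_cep17,
            "ihc_score": r.ihc_score,
            "fish_class": r.fish_class.value,
        }
        for r in records
    )
    frame.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[CohortRecord]:
    frame = pd.read_csv(path, dtype={"ihc_score": str})
    required = {"case_id", "batch_id", "role", "nfish_true"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"cohort CSV is missing columns {sorted(missing)}")
    return [
        CohortRecord(
            case_id=str(row.case_id),
            batch_id=str(row.batch_id),
            role=str(row.role),
            n_fish=float(row.nfish_true),
            her2_cep17=float(getattr(row, "her2_cep17", float("nan"))),
            ihc_score=str(getattr(row, "ihc_score", "")),
        )
        for row in frame.itertuples(index=False)
    ]


def write_measurements_csv(
    measurements: dict[str, Sequence[TileMeasurement]], path: str | Path
) -> None:
    """Measurement tables are the pipeline's interchange format."""
    rows = [
        {
            "case_id": case_id,
            "tile_row": m.tile_id[0],
            "tile_col": m.tile_id[1],
            "ck_mean": m.ck_mean,
            "her2_mean": m.her2_mean,
            "roi_area": m.roi_area,
            "valid": m.valid,
        }
        for case_id, tiles in measurements.items()
        for m in tiles
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_measurements_csv(path: str | Path) -> dict[str, list[TileMeasurement]]:
    frame = pd.read_csv(path)
    out: dict[str, list[TileMeasurement]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(str(row.case_id), []).append(
            TileMeasurement(
                tile_id=(int(row.tile_row), int(row.tile_col)),
                ck_mean=float(row.ck_mean),
                her2_mean=float(row.her2_mean),
                roi_area=int(row.roi_area),
                valid=bool(row.valid),
            )
        )
    return out
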