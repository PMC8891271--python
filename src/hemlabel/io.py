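"""Image, tile and manifest input/output.

Flat PNG/TIFF images are read with Pillow; pyramidal TIFF/SVS files go
through a tifffile-backed reader that exposes pyramid levels. Label
manifests are UTF-8 CSV files with a "." decimal separator, one row per
tile including discarded tiles (whose ``tile_path`` is empty).
"""
from __future__ import annotations

import json
from dataclasses import asdict, fields
from pathlib import Path
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import CoordinateError, ImageReadError, LevelError
from .types import TileLabel, TileRecord, as_rgb

_FLAT_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp"}
_PYRAMID_SUFFIXES = {".tif", ".tiff", ".svs"}

MANIFEST_COLUMNS = [f.name for f in fields(TileRecord)]


def read_image(path: str | Path, level: int = 0) -> np.ndarray:
    """Read an RGB slide image at the given pyramid level.

    Flat formats (PNG/JPEG/BMP) only have level 0. Tiled pyramidal TIFF and
    Aperio SVS files expose their stored resolution levels via tifffile.

    Parameters
    ----------
    path : file path
    level : pyramid level, 0 = full resolution

    Returns
    -------
    ``(H, W, 3)`` uint8 array.
    """
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in _PYRAMID_SUFFIXES:
            arr = _read_tiff_level(path, level)
        else:
            if level != 0:
                raise LevelError(
                    f"{path.name} is a flat image; only level 0 exists, "
                    f"requested level {level}"
                )
            with Image.open(path) as im:
                arr = np.asarray(im.convert("RGB"))
    except (LevelError, ImageReadError):
        raise
    except Exception as exc:  # corrupt file, unsupported codec, ...
        raise ImageReadError(f"could not read {path}: {exc}") from exc
    return as_rgb(arr)


def _read_tiff_level(path: Path, level: int) -> np.ndarray:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        levels = getattr(series, "levels", [series])
        if not 0 <= level < len(levels):
            raise LevelError(
                f"{path.name} has {len(levels)} pyramid level(s); "
                f"requested level {level}"
            )
        arr = levels[level].asarray()
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write an RGB or single-channel image losslessly (PNG/TIFF)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(image)).save(path)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean raster as a 0/255 single-channel PNG."""
    write_image((np.asarray(mask, dtype=bool) * np.uint8(255)), path)


def write_tiles(
    image: np.ndarray,
    records: Sequence[TileRecord],
    out_dir: str | Path,
) -> pd.DataFrame:
    """Cut non-discarded tiles out of ``image`` and write them as PNG.

    Every record yields a manifest row; discarded tiles get an empty
    ``tile_path`` and no file. Tile footprints must lie inside the image.
    """
    image = as_rgb(image)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h, w = image.shape[:2]
    rows = []
    for rec in records:
        px = rec.he_tile_px
        r0, c0 = rec.tile_row * px, rec.tile_col * px
        if r0 < 0 or c0 < 0 or r0 + px > h or c0 + px > w:
            raise CoordinateError(
                f"tile ({rec.tile_row}, {rec.tile_col}) at {px}px falls "
                f"outside a {h}x{w} image"
            )
        if rec.label is not TileLabel.DISCARDED:
            name = f"{rec.slide_id}_r{rec.tile_row}_c{rec.tile_col}.png"
            write_image(image[r0 : r0 + px, c0 : c0 + px], out_dir / name)
            rec.tile_path = str(out_dir / name)
        else:
            rec.tile_path = ""
        rows.append(asdict(rec))
    return _as_manifest(rows)


def _as_manifest(rows: Iterable[dict]) -> pd.DataFrame:
    df = pd.DataFrame(list(rows), columns=MANIFEST_COLUMNS)
    df["label"] = df["label"].map(
        lambda v: v.value if isinstance(v, TileLabel) else str(v)
    )
    return df


def records_to_manifest(records: Sequence[TileRecord]) -> pd.DataFrame:
    """Build a manifest DataFrame from tile records (no tile files)."""
    return _as_manifest(asdict(r) for r in records)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    """Write a label manifest as UTF-8 CSV with header."""
    _validate_manifest(manifest)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False, encoding="utf-8")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a label manifest CSV, restoring column dtypes."""
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"manifest not found: {path}")
    df = pd.read_csv(path, encoding="utf-8", keep_default_na=False)
    for col in ("tile_row", "tile_col", "he_tile_px", "label_tile_px"):
        df[col] = df[col].astype(int)
    for col in (
        "dab_positive_fraction",
        "mean_dab_od",
        "tissue_fraction_he",
        "tissue_fraction_ihc",
    ):
        df[col] = df[col].astype(float)
    _validate_manifest(df)
    return df


def _validate_manifest(df: pd.DataFrame) -> None:
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    key = df[["slide_id", "tile_row", "tile_col"]]
    if key.duplicated().any():
        raise ValueError("manifest rows must be unique on (slide_id, row, col)")
    bad = set(df["label"]) - {l.value for l in TileLabel}
    if bad:
        raise ValueError(f"unknown labels in manifest: {sorted(bad)}")


def manifest_to_records(df: pd.DataFrame) -> List[TileRecord]:
    """Inverse of :func:`records_to_manifest`."""
    return [
        TileRecord(**{k: row[k] for k in MANIFEST_COLUMNS})
        for _, row in df.iterrows()
    ]


def read_annotation_mask(path: str | Path, shape: tuple[int, int]) -> np.ndarray:
    """Read a pathologist cancer annotation as a boolean raster.

    Accepts a single-channel binary PNG mask of exactly ``shape``, or a
    GeoJSON file of polygons in H&E level-0 pixel coordinates (x = column,
    y = row) which is rasterized to ``shape``.
    """
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"annotation file not found: {path}")
    if path.suffix.lower() in {".json", ".geojson"}:
        return _rasterize_polygons(path, shape)
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    vals = np.unique(arr)
    if len(vals) > 2:
        raise ValueError(
            f"annotation mask must be binary; found {len(vals)} gray levels"
        )
    if arr.shape != tuple(shape):
        raise ValueError(
            f"annotation mask shape {arr.shape} does not match image "
            f"shape {tuple(shape)} (supply polygons to rasterize instead)"
        )
    return arr > 0


def _rasterize_polygons(path: Path, shape: tuple[int, int]) -> np.ndarray:
    # Pixel-center semantics: pixel (r, c) is inside iff its center
    # (r + 0.5, c + 0.5) falls within the polygon, so a rectangle spanning
    # x in [0, 50) covers exactly columns 0..49.
    from skimage.measure import grid_points_in_poly

    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict) and data.get("type") == "FeatureCollection":
        geoms = [f["geometry"] for f in data["features"]]
    elif isinstance(data, dict) and "coordinates" in data:
        geoms = [data]
    else:
        raise ValueError(f"unsupported annotation JSON structure in {path}")
    mask = np.zeros(tuple(shape), dtype=bool)
    for geom in geoms:
        if geom["type"] != "Polygon":
            raise ValueError(f"unsupported geometry type {geom['type']!r}")
        ring = np.asarray(geom["coordinates"][0], dtype=float)
        verts_rc = np.column_stack([ring[:, 1], ring[:, 0]]) - 0.5
        mask |= grid_points_in_poly(tuple(shape), verts_rc)
    return mask
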