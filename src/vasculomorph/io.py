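"""File formats: PNG tiles and masks, CSV/TSV tables, JSON artifacts.

Conventions: RGB tiles are 8-bit PNG; binary masks single-channel PNG with
0/255; pixel coordinates are 0-based, row-major (row, col); cohort tables
are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synthetic import GroundTruthTile


def write_image(path: str | Path, rgb: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(rgb, dtype=np.uint8))


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    img = iio.imread(Path(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img > 127


def write_tile(tile: GroundTruthTile, out_dir: str | Path, tile_id: str) -> None:
    """Write one synthetic tile: H&E/IHC PNGs, vessel mask, centroid truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image(out / f"{tile_id}_he.png", tile.rgb_he)
    write_image(out / f"{tile_id}_ihc.png", tile.rgb_ihc)
    write_mask(out / f"{tile_id}_vessel_mask.png", tile.vessel_mask)
    rows = []
    for cls, pts in (
        ("endothelial", tile.ec_centroids),
        ("lymphocyte", tile.lymph_centroids),
        ("cancer", tile.cancer_centroids),
    ):
        for r, c in pts:
            rows.append({"tile_id": tile_id, "class": cls, "row": r, "col": c})
    pd.DataFrame(rows, columns=["tile_id", "class", "row", "col"]).to_csv(
        out / f"{tile_id}_centroids.csv", index=False
    )


def write_transform(path: str | Path, matrix: np.ndarray) -> None:
    Path(path).write_text(json.dumps({"matrix": np.asarray(matrix).tolist()}))


def read_transform(path: str | Path) -> np.ndarray:
    return np.asarray(json.loads(Path(path).read_text())["matrix"], dtype=float)


def write_json(path: str | Path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def read_tsv(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", index_col=index_col)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(Path(path), sep="\t", index=index)
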