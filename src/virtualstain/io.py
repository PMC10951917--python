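"""Reading and writing stacks, masks and reports.

Stacks travel as multi-page TIFF (float32), targets as 2-page TIFF,
class masks as 8-bit PNG with the display palette black = background,
gray (128) = healthy, white (255) = apoptotic; nucleus reports and metric
tables are tab-delimited text.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .preprocessing import APOPTOTIC, BACKGROUND, HEALTHY

MASK_PALETTE = {BACKGROUND: 0, HEALTHY: 128, APOPTOTIC: 255}
_PALETTE_INV = {v: k for k, v in MASK_PALETTE.items()}


def write_stack(path, stack: np.ndarray):
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def read_stack(path) -> np.ndarray:
    arr = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    return arr[None] if arr.ndim == 2 else arr


def write_mask_png(path, class_mask: np.ndarray):
    img = np.zeros(class_mask.shape, dtype=np.uint8)
    for cls, value in MASK_PALETTE.items():
        img[class_mask == cls] = value
    iio.imwrite(str(path), img)


def read_mask_png(path) -> np.ndarray:
    img = np.asarray(iio.imread(str(path)))
    if img.ndim == 3:
        img = img[..., 0]
    out = np.full(img.shape, BACKGROUND, dtype=np.int64)
    for value, cls in _PALETTE_INV.items():
        out[img == value] = cls
    return out


def write_table(path, rows: list[dict], columns: list[str] | None = None):
    columns = columns or (list(rows[0]) if rows else [])
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def write_manifest(path, entries: list[dict]):
    write_table(path, entries)


def read_config_yaml(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh) or {}
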