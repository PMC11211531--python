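"""Readers and writers shared by the CLI: plain-text images, tables, reports.

Stain and deposition maps are written as plain (ASCII) portable graymaps
(PGM, magic ``P2``) so every artifact stays text; arbitrary scanned images
(PNG etc.) can be imported through a luminance threshold.  Tables are
comma-separated with units in the header names; reports are JSON key-value
documents.  Lengths in exported tables are millimetres, pressures MPa,
matching field convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .coverage import AreaLayout, StainImage

MM = 1e-3
MPA = 1e6


def write_pgm(path, values: np.ndarray, maxval: int = 255) -> None:
    """Write a 2-d array (0..1 or bool) as a plain-text PGM (P2)."""
    arr = np.asarray(values)
    if arr.dtype == bool:
        arr = arr.astype(float)
    arr = np.clip(arr, 0.0, 1.0)
    gray = np.round(arr * maxval).astype(int)
    lines = ["P2", f"{gray.shape[1]} {gray.shape[0]}", str(maxval)]
    lines += [" ".join(map(str, row)) for row in gray]
    Path(path).write_text("\n".join(lines) + "\n")


def read_pgm(path) -> np.ndarray:
    """Read a plain-text PGM (P2) back into a float array in [0, 1]."""
    tokens = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0]
        tokens.extend(line.split())
    if not tokens or tokens[0] != "P2":
        raise ValueError(f"{path} is not a plain (P2) PGM file")
    ncol, nrow, maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
    data = np.array(tokens[4:4 + nrow * ncol], dtype=float).reshape(nrow, ncol)
    return data / maxval


def write_stain_image(path, img: StainImage) -> None:
    write_pgm(path, img.pixels)


def read_stain_image(path, resolution: float, origin=(0.0, 0.0),
                     layout: AreaLayout | None = None,
                     threshold: float = 0.5) -> StainImage:
    """Load a stain image from a plain PGM (stained where value >= threshold)."""
    data = read_pgm(path)
    return StainImage(pixels=data >= threshold, resolution=resolution,
                      origin=origin, layout=layout or AreaLayout())


def import_scanned_image(path, resolution: float, origin=(0.0, 0.0),
                         layout: AreaLayout | None = None,
                         threshold: float = 0.5,
                         stained_is_dark: bool = True) -> StainImage:
    """Import an arbitrary raster scan via a luminance threshold.

    Water-sensitive paper stains dark blue on a yellow card, so by default a
    pixel is stained where its normalized luminance falls below the
    threshold.
    """
    from PIL import Image

    lum = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
    stained = lum < threshold if stained_is_dark else lum >= threshold
    return StainImage(pixels=stained, resolution=resolution, origin=origin,
                      layout=layout or AreaLayout())


def write_report(path, data: dict) -> None:
    """Write a machine-readable key-value report (JSON)."""
    Path(path).write_text(json.dumps(_plain(data), indent=2, sort_keys=True) + "\n")


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_table(path, df) -> None:
    """Write a DataFrame as comma-separated text (units belong in headers)."""
    df.to_csv(path, index=False)
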