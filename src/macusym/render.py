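"""Gray-scale asymmetry-map rendering and the 4×4 subject panel.

Retained (negative) differences are drawn on a linear gray ramp from white
(zero difference) to black (thinning at or beyond the layer cut-off):
``g = round(255 * (1 - min(|diff|, cutoff)/cutoff))``. Excluded cells —
non-negative differences and the inter-hemispheric centerline — render
white; missing cells render a distinct sentinel gray (128 by default).

The subject panel arrays the 16 maps in a 4×4 matrix: rows RNFL, GCIPL,
GCC, total retina; columns inter-hemispheric right eye, inter-ocular right
eye, inter-ocular left eye, inter-hemispheric left eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .asymmetry import (
    CellState,
    AsymmetryMap,
    interhemispheric_difference,
    interocular_difference,
)
from .grids import Eye, Layer, SubjectRecord

__all__ = ["RenderSpec", "render_map", "render_panel", "subject_panel_maps",
           "save_pgm", "save_png"]

PANEL_ROWS = (Layer.RNFL, Layer.GCIPL, Layer.GCC, Layer.TOTAL_RETINA)
#: (eye, mode-tag) per panel column, left to right.
PANEL_COLS = (
    (Eye.OD, "INTERHEMISPHERIC"),
    (Eye.OD, "INTEROCULAR"),
    (Eye.OS, "INTEROCULAR"),
    (Eye.OS, "INTERHEMISPHERIC"),
)


@dataclass(frozen=True)
class RenderSpec:
    pixel_scale: int = 4
    separator_px: int = 2
    margin_px: int = 4
    missing_gray: int = 128
    separator_gray: int = 200

    def __post_init__(self) -> None:
        if self.pixel_scale < 1:
            raise ValueError("pixel_scale must be >= 1")


def render_map(amap: AsymmetryMap, spec: RenderSpec = RenderSpec(pixel_scale=1, separator_px=0)) -> np.ndarray:
    """Render one asymmetry map to a uint8 gray image array.

    Deterministic; gray level is monotone non-increasing in |diff| for
    retained cells.
    """
    if amap.cutoff_um <= 0:
        raise ValueError("cutoff must be positive")
    frac = np.zeros_like(amap.diffs)
    retained = amap.states == CellState.RETAINED
    frac[retained] = np.minimum(np.abs(amap.diffs[retained]), amap.cutoff_um) / amap.cutoff_um
    gray = np.rint(255.0 * (1.0 - frac)).astype(np.uint8)
    gray[amap.states == CellState.EXCLUDED_NONNEG] = 255
    gray[amap.states == CellState.EXCLUDED_CENTERLINE] = 255
    gray[amap.states == CellState.MISSING] = np.uint8(spec.missing_gray)
    if spec.pixel_scale > 1:
        gray = np.kron(gray, np.ones((spec.pixel_scale, spec.pixel_scale), dtype=np.uint8))
    return gray


def subject_panel_maps(rec: SubjectRecord) -> dict[tuple[Layer, int], AsymmetryMap]:
    """The 16 asymmetry maps of the 4×4 panel, keyed by (layer, column)."""
    maps = {}
    for li, layer in enumerate(PANEL_ROWS):
        for ci, (eye, tag) in enumerate(PANEL_COLS):
            if tag == "INTERHEMISPHERIC":
                amap = interhemispheric_difference(rec.grid(eye, layer))
            else:
                amap = interocular_difference(rec.grid(eye, layer), rec.grid(eye.fellow, layer))
            maps[(layer, ci)] = amap
    return maps


def render_panel(maps: dict[tuple[Layer, int], AsymmetryMap],
                 spec: RenderSpec = RenderSpec()) -> np.ndarray:
    """Compose the 16 maps into the 4×4 panel image (uint8 array)."""
    for layer in PANEL_ROWS:
        for ci in range(4):
            if (layer, ci) not in maps:
                raise ValueError(f"panel missing map for {layer.value}, column {ci}")
    tiles = [[render_map(maps[(layer, ci)], spec) for ci in range(4)] for layer in PANEL_ROWS]
    tile_h, tile_w = tiles[0][0].shape
    sep, mar = spec.separator_px, spec.margin_px
    height = 2 * mar + 4 * tile_h + 3 * sep
    width = 2 * mar + 4 * tile_w + 3 * sep
    panel = np.full((height, width), np.uint8(spec.separator_gray))
    for ri, row in enumerate(tiles):
        for ci, tile in enumerate(row):
            r0 = mar + ri * (tile_h + sep)
            c0 = mar + ci * (tile_w + sep)
            panel[r0 : r0 + tile_h, c0 : c0 + tile_w] = tile
    return panel


def save_pgm(image: np.ndarray, path: str | Path) -> None:
    """Write a uint8 gray image as plain-text PGM (P2); bit-reproducible."""
    image = np.asarray(image, dtype=np.uint8)
    path = Path(path)
    with path.open("w", encoding="ascii") as fh:
        fh.write(f"P2\n{image.shape[1]} {image.shape[0]}\n255\n")
        for row in image:
            fh.write(" ".join(str(int(v)) for v in row))
            fh.write("\n")


def save_png(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(Path(path))
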