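"""Inter-ocular and inter-hemispheric superpixel asymmetry maps.

The core computation: for every superpixel of a target eye's macular grid,
subtract the thickness of the anatomically corresponding superpixel — the
horizontally mirrored cell of the fellow eye (inter-ocular mode) or the
vertically mirrored cell across the foveal horizontal (inter-hemispheric
mode). Only negative differences (relative thinning) are retained; a
retained cell whose decrease exceeds the layer cut-off (20 μm for GCIPL,
40 μm for RNFL, GCC and total retina) is a "black superpixel".

Cell states on an :class:`AsymmetryMap`:

* ``RETAINED`` — negative difference, enters averages and counts;
* ``EXCLUDED_NONNEG`` — difference >= 0, excluded from analysis;
* ``EXCLUDED_CENTERLINE`` — the central row of an inter-hemispheric map,
  which lies on the symmetry axis and has no mirror partner;
* ``MISSING`` — either source superpixel missing; never imputed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .grids import Eye, Layer, ThicknessGrid, mirror_horizontal

__all__ = [
    "Mode",
    "CellState",
    "AsymmetryMap",
    "AsymmetryIndices",
    "default_cutoff",
    "interocular_difference",
    "interhemispheric_difference",
    "compute_indices",
    "analyze_subject",
]


class Mode(str, enum.Enum):
    INTEROCULAR = "INTEROCULAR"
    INTERHEMISPHERIC = "INTERHEMISPHERIC"


class CellState(enum.IntEnum):
    RETAINED = 1
    EXCLUDED_NONNEG = 2
    EXCLUDED_CENTERLINE = 3
    MISSING = 4


#: Black-superpixel cut-offs (μm of thinning) per layer.
_CUTOFFS = {
    Layer.RNFL: 40.0,
    Layer.GCIPL: 20.0,
    Layer.GCC: 40.0,
    Layer.TOTAL_RETINA: 40.0,
}


def default_cutoff(layer: Layer) -> float:
    """Black-superpixel cut-off in μm: GCIPL 20; RNFL, GCC, total retina 40."""
    try:
        return _CUTOFFS[Layer(layer)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unknown layer: {layer!r}") from exc


@dataclass(frozen=True)
class AsymmetryMap:
    """Signed per-superpixel difference map with cell states."""

    diffs: np.ndarray
    states: np.ndarray
    mode: Mode
    layer: Layer
    cutoff_um: float

    def __post_init__(self) -> None:
        if self.diffs.shape != self.states.shape:
            raise ValueError("diffs and states must have the same shape")
        if self.cutoff_um <= 0:
            raise ValueError("cutoff_um must be positive")

    @property
    def retained_mask(self) -> np.ndarray:
        return self.states == CellState.RETAINED

    @property
    def retained_diffs(self) -> np.ndarray:
        return self.diffs[self.retained_mask]


@dataclass(frozen=True)
class AsymmetryIndices:
    """Per-map summary indices.

    ``avg_negative_diff_um`` is the mean over retained (negative) cells
    only; when no cell is retained it is reported as 0.0 with
    ``no_negative_cells`` set, so downstream group statistics stay total.
    """

    avg_negative_diff_um: float
    n_negative: int
    n_black: int
    n_missing: int
    n_excluded: int
    no_negative_cells: bool = False


def _classify(diffs: np.ndarray, missing: np.ndarray, centerline_row: int | None = None):
    states = np.full(diffs.shape, CellState.EXCLUDED_NONNEG, dtype=np.int16)
    states[diffs < 0] = CellState.RETAINED
    if centerline_row is not None:
        states[centerline_row, :] = CellState.EXCLUDED_CENTERLINE
    states[missing] = CellState.MISSING
    out = diffs.copy()
    out[missing] = np.nan
    return out, states


def interocular_difference(target: ThicknessGrid, contralateral: ThicknessGrid,
                           cutoff_um: float | None = None) -> AsymmetryMap:
    """Difference map of the target eye against the mirrored fellow eye.

    ``diff(r, c) = target(r, c) − contralateral(r, ncols−1−c)``: mirrored
    column pairs are the anatomically corresponding superpixels of fellow
    eyes. Non-negative differences are excluded; a cell missing in either
    eye is missing in the map.
    """
    if target.shape != contralateral.shape:
        raise ValueError(f"shape mismatch: {target.shape} vs {contralateral.shape}")
    if target.layer is not contralateral.layer:
        raise ValueError(f"layer mismatch: {target.layer} vs {contralateral.layer}")
    if target.laterality is contralateral.laterality:
        raise ValueError("target and contralateral grids have the same laterality")
    mirrored = mirror_horizontal(contralateral)
    missing = np.isnan(target.values) | np.isnan(mirrored.values)
    with np.errstate(invalid="ignore"):
        diffs = target.values - mirrored.values
    diffs, states = _classify(diffs, missing)
    return AsymmetryMap(
        diffs=diffs,
        states=states,
        mode=Mode.INTEROCULAR,
        layer=target.layer,
        cutoff_um=default_cutoff(target.layer) if cutoff_um is None else cutoff_um,
    )


def interhemispheric_difference(grid: ThicknessGrid,
                                cutoff_um: float | None = None) -> AsymmetryMap:
    """Difference map of each hemifield against its vertical mirror.

    The symmetry axis is the horizontal through the foveal pit, i.e. the
    central row of the odd-sized fovea-centered grid; that row has no
    mirror partner and is excluded. For every other cell,
    ``diff(r, c) = grid(r, c) − grid(nrows−1−r, c)``, so the map is
    antisymmetric before negative selection.
    """
    nrows = grid.shape[0]
    if nrows % 2 == 0:
        raise ValueError(f"inter-hemispheric analysis needs an odd row count, got {nrows}")
    center = nrows // 2
    flipped = grid.values[::-1, :]
    missing = np.isnan(grid.values) | np.isnan(flipped)
    with np.errstate(invalid="ignore"):
        diffs = grid.values - flipped
    diffs, states = _classify(diffs, missing, centerline_row=center)
    return AsymmetryMap(
        diffs=diffs,
        states=states,
        mode=Mode.INTERHEMISPHERIC,
        layer=grid.layer,
        cutoff_um=default_cutoff(grid.layer) if cutoff_um is None else cutoff_um,
    )


def compute_indices(amap: AsymmetryMap, cutoff_inclusive: bool = False) -> AsymmetryIndices:
    """Average negative difference and black-superpixel count of one map.

    A black superpixel is a retained cell whose thinning is over the
    cut-off: ``diff < −cutoff`` under the default strict rule
    (``diff <= −cutoff`` with ``cutoff_inclusive``).
    """
    retained = amap.retained_diffs
    n_neg = retained.size
    if cutoff_inclusive:
        n_black = int(np.sum(retained <= -amap.cutoff_um))
    else:
        n_black = int(np.sum(retained < -amap.cutoff_um))
    n_missing = int(np.sum(amap.states == CellState.MISSING))
    n_excluded = int(
        np.sum((amap.states == CellState.EXCLUDED_NONNEG)
               | (amap.states == CellState.EXCLUDED_CENTERLINE))
    )
    if n_neg == 0:
        return AsymmetryIndices(0.0, 0, n_black, n_missing, n_excluded, no_negative_cells=True)
    return AsymmetryIndices(float(retained.mean()), int(n_neg), n_black, n_missing, n_excluded)


def analyze_subject(rec, cutoff_inclusive: bool = False,
                    with_maps: bool = False):
    """All eight asymmetry index sets (4 layers × 2 modes) for the target eye.

    Inter-ocular mode compares the target eye against its fellow;
    inter-hemispheric mode uses the target eye's own grid. With
    ``with_maps`` the :class:`AsymmetryMap` objects are returned alongside
    the indices.
    """
    target_eye: Eye = rec.target_eye
    fellow = target_eye.fellow
    indices: dict[tuple[Layer, Mode], AsymmetryIndices] = {}
    maps: dict[tuple[Layer, Mode], AsymmetryMap] = {}
    for layer in Layer:
        amap_io = interocular_difference(rec.grid(target_eye, layer), rec.grid(fellow, layer))
        amap_ih = interhemispheric_difference(rec.grid(target_eye, layer))
        indices[(layer, Mode.INTEROCULAR)] = compute_indices(amap_io, cutoff_inclusive)
        indices[(layer, Mode.INTERHEMISPHERIC)] = compute_indices(amap_ih, cutoff_inclusive)
        maps[(layer, Mode.INTEROCULAR)] = amap_io
        maps[(layer, Mode.INTERHEMISPHERIC)] = amap_ih
    if with_maps:
        return indices, maps
    return indices
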