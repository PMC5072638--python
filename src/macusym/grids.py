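"""Thickness-grid data model, CSV I/O, and coordinate conventions.

A macular thickness map is a rectangular grid of "superpixels": each cell
holds the average layer thickness (μm) over a 200 × 200 μm square of the
fundus. Grids are stored fundus-view as displayed by the device: row 0 is
the superior-most row, columns run left to right across the displayed
image. The package never assumes which column side is nasal; inter-ocular
correspondence between fellow eyes is defined purely by horizontal
mirroring, which is anatomically correct regardless of display side.

Coordinates are 0-based ``(row, col)``; windows are inclusive. Missing
cells (e.g. local segmentation failure) are represented as NaN and are
never silently imputed by any operation in this module.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Layer",
    "Eye",
    "Group",
    "DiseaseLaterality",
    "ThicknessGrid",
    "WideScanGrid",
    "SubjectRecord",
    "CohortManifest",
    "GridFormatError",
    "GridValidationError",
    "read_grid_csv",
    "write_grid_csv",
    "extract_macular_grid",
    "mirror_horizontal",
]

#: Edge length (superpixels) of the macular analysis grid: 6.2 mm at 0.2 mm pitch.
MACULAR_GRID_SIZE = 31

#: Default wide-scan grid shape: 12 × 9 mm at 0.2 mm pitch -> 45 rows × 60 cols.
WIDE_SCAN_SHAPE = (45, 60)


class Layer(str, enum.Enum):
    """Retinal layers measured on the macular grid."""

    RNFL = "RNFL"
    GCIPL = "GCIPL"
    GCC = "GCC"
    TOTAL_RETINA = "TOTAL_RETINA"


class Eye(str, enum.Enum):
    OD = "OD"  # right eye
    OS = "OS"  # left eye

    @property
    def fellow(self) -> "Eye":
        return Eye.OS if self is Eye.OD else Eye.OD


class Group(str, enum.Enum):
    NORMAL = "NORMAL"
    GLAUCOMA = "GLAUCOMA"


class DiseaseLaterality(str, enum.Enum):
    NONE = "NONE"
    UNILATERAL = "UNILATERAL"
    BILATERAL = "BILATERAL"


class GridFormatError(ValueError):
    """Raised for malformed grid files (ragged rows, non-numeric cells)."""


class GridValidationError(ValueError):
    """Raised when grid contents violate a physical invariant."""


def _validate_values(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
        raise GridValidationError(f"grid must be 2-D with >=1 rows/cols, got shape {values.shape}")
    finite = np.isfinite(values)
    if np.any(np.isinf(values)):
        raise GridValidationError("grid contains non-finite (inf) thickness values")
    if np.any(values[finite] < 0):
        raise GridValidationError("negative thickness values are not physical")
    return values


@dataclass(frozen=True)
class ThicknessGrid:
    """One eye's single-layer gridded thickness map.

    ``values`` is in μm, row 0 superior; NaN marks a missing superpixel.
    """

    values: np.ndarray
    layer: Layer
    laterality: Eye
    superpixel_size_mm: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _validate_values(self.values))
        object.__setattr__(self, "layer", Layer(self.layer))
        object.__setattr__(self, "laterality", Eye(self.laterality))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def mean_thickness(self) -> float:
        """Mean over non-missing cells, μm."""
        if self.n_missing == self.values.size:
            raise GridValidationError("all cells missing; mean thickness undefined")
        return float(np.nanmean(self.values))


@dataclass(frozen=True)
class WideScanGrid:
    """Posterior-pole wide-scan thickness grid (12 × 9 mm by default).

    ``fovea_rc`` is the 0-based (row, col) of the superpixel whose center is
    nearest the foveal pit; fovea localization is an input, not computed.
    """

    values: np.ndarray
    layer: Layer
    laterality: Eye
    fovea_rc: tuple[int, int]
    superpixel_size_mm: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _validate_values(self.values))
        object.__setattr__(self, "layer", Layer(self.layer))
        object.__setattr__(self, "laterality", Eye(self.laterality))
        r, c = self.fovea_rc
        nr, nc = self.values.shape
        if not (0 <= r < nr and 0 <= c < nc):
            raise GridValidationError(f"fovea_rc {self.fovea_rc} outside grid of shape {(nr, nc)}")


@dataclass(frozen=True)
class SubjectRecord:
    """Paired-eye, four-layer grids for one study subject."""

    subject_id: str
    group: Group
    target_eye: Eye
    disease_laterality: DiseaseLaterality
    grids: Mapping[tuple[Eye, Layer], ThicknessGrid] = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))
        object.__setattr__(self, "target_eye", Eye(self.target_eye))
        object.__setattr__(self, "disease_laterality", DiseaseLaterality(self.disease_laterality))
        for eye in Eye:
            for layer in Layer:
                if (eye, layer) not in self.grids:
                    raise GridValidationError(f"missing grid for {eye.value}/{layer.value}")
        if self.group is Group.NORMAL and self.disease_laterality is not DiseaseLaterality.NONE:
            raise GridValidationError("normal subjects must have disease_laterality NONE")

    def grid(self, eye: Eye, layer: Layer) -> ThicknessGrid:
        return self.grids[(Eye(eye), Layer(layer))]


def _format_cell(x: float) -> str:
    if np.isnan(x):
        return ""
    # shortest round-trip repr; integers without trailing '.0'
    if float(x) == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def read_grid_csv(path: str | Path, layer: Layer, laterality: Eye) -> ThicknessGrid:
    """Read a plain numeric CSV matrix as a :class:`ThicknessGrid`.

    Row 0 of the file is the superior-most row. Empty cells denote missing
    superpixels. Ragged rows raise :class:`GridFormatError`; negative
    thickness raises :class:`GridValidationError`.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").split("\n")
    if lines and lines[-1] == "":
        lines.pop()  # trailing newline; earlier blank lines are 1-col missing rows
    rows: list[list[float]] = []
    for i, record in enumerate(csv.reader(lines)):
        if not record:
            record = [""]
        if rows and len(record) != len(rows[0]):
            raise GridFormatError(
                f"{path}: ragged row {i}: {len(record)} fields, expected {len(rows[0])}"
            )
        parsed = []
        for j, tok in enumerate(record):
            tok = tok.strip()
            if tok == "":
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(tok))
            except ValueError as exc:
                raise GridFormatError(f"{path}: non-numeric cell at row {i}, col {j}: {tok!r}") from exc
        rows.append(parsed)
    if not rows:
        raise GridFormatError(f"{path}: empty grid file")
    return ThicknessGrid(values=np.array(rows, dtype=float), layer=layer, laterality=laterality)


def write_grid_csv(grid: ThicknessGrid, path: str | Path) -> None:
    """Write a grid as a headerless CSV matrix (missing cells empty).

    Canonical formatting: shortest round-trip decimal repr, '\\n' line ends;
    ``write_grid_csv`` after ``read_grid_csv`` reproduces a canonical file
    byte-identically.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        for row in grid.values:
            fh.write(",".join(_format_cell(x) for x in row))
            fh.write("\n")


def extract_macular_grid(wide: WideScanGrid, half_width: int = 15) -> ThicknessGrid:
    """Cut the fovea-centered macular window out of a wide scan.

    Returns the ``(2*half_width+1)``-square window centered on
    ``wide.fovea_rc`` (31×31 for the default, i.e. 6.2 × 6.2 mm); the fovea
    lands in the central superpixel.
    """
    r0, c0 = wide.fovea_rc
    nr, nc = wide.values.shape
    lo_r, hi_r = r0 - half_width, r0 + half_width
    lo_c, hi_c = c0 - half_width, c0 + half_width
    if lo_r < 0:
        raise IndexError(f"macular window exceeds superior edge: needs row {lo_r}")
    if hi_r >= nr:
        raise IndexError(f"macular window exceeds inferior edge: needs row {hi_r} of {nr}")
    if lo_c < 0:
        raise IndexError(f"macular window exceeds left edge: needs col {lo_c}")
    if hi_c >= nc:
        raise IndexError(f"macular window exceeds right edge: needs col {hi_c} of {nc}")
    window = wide.values[lo_r : hi_r + 1, lo_c : hi_c + 1].copy()
    return ThicknessGrid(
        values=window,
        layer=wide.layer,
        laterality=wide.laterality,
        superpixel_size_mm=wide.superpixel_size_mm,
    )


def mirror_horizontal(grid: ThicknessGrid) -> ThicknessGrid:
    """Flip a grid left-right into fellow-eye-equivalent orientation.

    Column ``c`` maps to ``ncols-1-c``; rows are unchanged; the laterality
    label is flipped. Mirroring twice is the identity.
    """
    return replace(grid, values=grid.values[:, ::-1].copy(), laterality=grid.laterality.fellow)


# ---------------------------------------------------------------------------
# Cohort manifest

_MANIFEST_META = ["subject_id", "group", "target_eye", "disease_laterality"]


def _path_col(eye: Eye, layer: Layer) -> str:
    return f"path_{eye.value}_{layer.value}"


_MANIFEST_COLS = _MANIFEST_META + [_path_col(e, l) for e in Eye for l in Layer]


@dataclass
class CohortManifest:
    """Table of subjects with per-eye/per-layer grid file paths.

    Paths are stored relative to ``root`` (the manifest's directory when
    loaded from disk).
    """

    table: pd.DataFrame
    root: Path = Path(".")

    def __post_init__(self) -> None:
        missing = [c for c in _MANIFEST_COLS if c not in self.table.columns]
        if missing:
            raise GridFormatError(f"manifest missing columns: {missing}")
        ids = self.table["subject_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise GridValidationError(f"duplicate subject_id in manifest: {dup!r}")
        self.root = Path(self.root)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def load(cls, path: str | Path) -> "CohortManifest":
        path = Path(path)
        table = pd.read_csv(path, dtype=str)
        return cls(table=table, root=path.parent)

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False, lineterminator="\n")

    def load_subject(self, row: pd.Series) -> SubjectRecord:
        grids = {}
        for eye in Eye:
            for layer in Layer:
                p = self.root / row[_path_col(eye, layer)]
                if not p.exists():
                    raise FileNotFoundError(f"grid file not found: {p}")
                grids[(eye, layer)] = read_grid_csv(p, layer=layer, laterality=eye)
        return SubjectRecord(
            subject_id=row["subject_id"],
            group=Group(row["group"]),
            target_eye=Eye(row["target_eye"]),
            disease_laterality=DiseaseLaterality(row["disease_laterality"]),
            grids=grids,
        )

    def iter_subjects(self):
        for _, row in self.table.iterrows():
            yield self.load_subject(row)

    @staticmethod
    def row_for(subject: SubjectRecord, paths: Mapping[tuple[Eye, Layer], str]) -> dict:
        row = {
            "subject_id": subject.subject_id,
            "group": subject.group.value,
            "target_eye": subject.target_eye.value,
            "disease_laterality": subject.disease_laterality.value,
        }
        for eye in Eye:
            for layer in Layer:
                row[_path_col(eye, layer)] = paths[(eye, layer)]
        return row
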