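"""Patch-probability grids: reading, binarization, and lattice alignment.

A whole-slide image is processed by two patch classifiers operating at
different physical patch sizes (tumor: 87.5 µm, lymphocyte: 50 µm).  Each
produces a rectangular grid of per-patch probabilities.  This module reads
those grids (CSV matrices or grayscale PNGs with a YAML sidecar), binarizes
them at a probability threshold, and replicates both binary grids onto a
common fine lattice whose pitch is the greatest common divisor of the two
patch sizes (12.5 µm for the 87.5/50 pair) so they can be overlaid cell for
cell.

Coordinates are row-major and 0-based; patch (i, j) covers the half-open
physical square [j*s, (j+1)*s) x [i*s, (i+1)*s) µm, origins co-registered at
the top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .errors import AlignmentError, FormatError, ParameterError, ValidationError

__all__ = [
    "HeatmapGrid",
    "BinaryGrid",
    "LatticePair",
    "read_heatmap",
    "write_heatmap",
    "read_sidecar",
    "write_sidecar",
    "binarize",
    "resample_to_common_lattice",
    "TUMOR_PATCH_UM",
    "LYMPH_PATCH_UM",
]

#: Physical edge length of one tumor-model patch (µm); 350 px at 40x.
TUMOR_PATCH_UM = 87.5
#: Physical edge length of one lymphocyte-model patch (µm); 200 px at 40x.
LYMPH_PATCH_UM = 50.0


@dataclass
class HeatmapGrid:
    """Rectangular grid of patch probabilities for one slide.

    Parameters
    ----------
    values
        2-D float array of probabilities in [0, 1].  Cells where
        ``tissue_mask`` is False may hold any value (they are ignored).
    patch_size_um
        Physical edge length of one patch in µm; must be positive.
    slide_id
        Identifier of the source slide.
    tissue_mask
        Optional boolean array of the same shape marking patches with
        analyzable tissue.  ``None`` means every patch is analyzable.
    """

    values: np.ndarray
    patch_size_um: float
    slide_id: str = ""
    tissue_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("heatmap values must form a 2-D grid")
        if self.patch_size_um <= 0:
            raise ValidationError("patch_size_um must be positive")
        if self.tissue_mask is not None:
            self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
            if self.tissue_mask.shape != self.values.shape:
                raise ValidationError("tissue_mask shape must match values")
        check = (
            self.values
            if self.tissue_mask is None
            else self.values[self.tissue_mask]
        )
        if check.size and (
            np.nanmin(check) < -1e-9 or np.nanmax(check) > 1 + 1e-9
        ):
            raise ValidationError("probabilities must lie in [0, 1]")
        np.clip(self.values, 0.0, 1.0, out=self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class BinaryGrid:
    """Thresholded patch grid: True where the classifier called positive."""

    values: np.ndarray
    patch_size_um: float
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValidationError("binary grid must be 2-D")
        if self.patch_size_um <= 0:
            raise ValidationError("patch_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class LatticePair:
    """Tumor and lymphocyte binary grids resampled onto one fine lattice."""

    tumor: BinaryGrid
    lymph: BinaryGrid
    cell_size_um: float

    def __post_init__(self) -> None:
        if self.tumor.shape != self.lymph.shape:
            raise AlignmentError("tumor and lymph lattices must share a shape")


def read_heatmap(
    path: str | Path, patch_size_um: float, slide_id: str = ""
) -> HeatmapGrid:
    """Read a probability heatmap from a CSV matrix or grayscale PNG.

    CSV files are headerless comma-separated numeric matrices.  PNG pixel
    values are mapped linearly to probability as ``value / max_intensity``
    (255 for 8-bit, 65535 for 16-bit); no gamma is applied so round trips
    are bit-exact.
    """
    path = Path(path)
    if path.suffix.lower() == ".png":
        img = Image.open(path)
        if img.mode == "I;16":
            arr = np.asarray(img, dtype=np.uint16)
            values = arr / np.float64(65535)
        elif img.mode in ("L", "I", "P"):
            arr = np.asarray(img.convert("L"), dtype=np.uint8)
            values = arr / np.float64(255)
        else:
            raise FormatError(f"unsupported PNG mode {img.mode!r}; need grayscale")
        return HeatmapGrid(values, patch_size_um, slide_id)

    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rows.append([float(tok) for tok in line.split(",")])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric entry") from exc
    if not rows:
        raise FormatError(f"{path}: empty heatmap")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(
            f"{path}: ragged CSV (row lengths {sorted(widths)}); "
            "heatmaps must be rectangular"
        )
    values = np.array(rows, dtype=float)
    if values.min() < -1e-9 or values.max() > 1 + 1e-9:
        raise ValidationError(f"{path}: probabilities outside [0, 1]")
    return HeatmapGrid(values, patch_size_um, slide_id)


def write_heatmap(grid: HeatmapGrid, path: str | Path) -> None:
    """Write a heatmap as a headerless CSV matrix (full float precision)."""
    np.savetxt(path, grid.values, delimiter=",", fmt="%.17g")


def read_sidecar(path: str | Path) -> dict:
    """Read the YAML metadata sidecar {slide_id, patch_size_um, magnification}."""
    with open(path) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict) or "patch_size_um" not in meta:
        raise FormatError(f"{path}: sidecar must be a mapping with patch_size_um")
    return meta


def write_sidecar(path: str | Path, slide_id: str, patch_size_um: float,
                  magnification: float = 40.0) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"slide_id": slide_id, "patch_size_um": float(patch_size_um),
             "magnification": float(magnification)},
            fh,
        )


def binarize(grid: HeatmapGrid, threshold: float = 0.5) -> BinaryGrid:
    """Threshold a probability grid: positive iff probability >= threshold.

    Patches with probability >= 50% are considered positive by default and
    patches below it negative.  Cells outside the tissue mask are always
    negative.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError("threshold must lie in [0, 1]")
    positive = grid.values >= threshold
    if grid.tissue_mask is not None:
        positive &= grid.tissue_mask
    return BinaryGrid(positive, grid.patch_size_um, grid.slide_id)


def _gcd_um(a: float, b: float) -> float:
    """Exact greatest common divisor of two physical pitches in µm."""
    fa, fb = Fraction(a).limit_denominator(10**6), Fraction(b).limit_denominator(10**6)
    den = fa.denominator * fb.denominator
    g = gcd(fa.numerator * fb.denominator, fb.numerator * fa.denominator)
    return g / den


def _replicate(src: BinaryGrid, pitch: float, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-source replication of a coarse grid onto the fine lattice.

    Fine cell (i, j) takes the value of the source patch containing its
    top-left corner; cells beyond the source extent are False.
    """
    out = np.zeros(shape, dtype=bool)
    rows = np.floor(np.arange(shape[0]) * pitch / src.patch_size_um).astype(int)
    cols = np.floor(np.arange(shape[1]) * pitch / src.patch_size_um).astype(int)
    rin = rows < src.shape[0]
    cin = cols < src.shape[1]
    out[np.ix_(rin, cin)] = src.values[np.ix_(rows[rin], cols[cin])]
    return out


def resample_to_common_lattice(
    tumor: BinaryGrid, lymph: BinaryGrid
) -> LatticePair:
    """Replicate both binary grids onto their GCD lattice.

    The common pitch is the greatest common divisor of the two patch sizes
    (12.5 µm for 87.5/50).  Physical extents may disagree by up to one
    coarse patch per dimension — model tiling truncates slide edges
    differently per patch size — and are cropped to the overlapping extent.

    Raises
    ------
    AlignmentError
        If the two extents differ by more than one coarse patch in either
        dimension, or the slide ids differ.
    """
    if tumor.slide_id != lymph.slide_id:
        raise AlignmentError(
            f"slide ids differ: {tumor.slide_id!r} vs {lymph.slide_id!r}"
        )
    pitch = _gcd_um(tumor.patch_size_um, lymph.patch_size_um)
    tol = max(tumor.patch_size_um, lymph.patch_size_um)
    shape = []
    for axis in (0, 1):
        ext_t = tumor.shape[axis] * tumor.patch_size_um
        ext_l = lymph.shape[axis] * lymph.patch_size_um
        if abs(ext_t - ext_l) > tol + 1e-9:
            raise AlignmentError(
                f"axis {axis}: extents {ext_t} µm vs {ext_l} µm differ by "
                f"more than one coarse patch ({tol} µm)"
            )
        shape.append(int(round(min(ext_t, ext_l) / pitch)))
    shape = tuple(shape)
    fine_t = _replicate(tumor, pitch, shape)
    fine_l = _replicate(lymph, pitch, shape)
    return LatticePair(
        BinaryGrid(fine_t, pitch, tumor.slide_id),
        BinaryGrid(fine_l, pitch, lymph.slide_id),
        pitch,
    )
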