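"""Tumor-TIL map composition, percent infiltration, and rendering.

Overlaying the binarized tumor and lymphocyte grids on the common lattice
partitions each cell into one of four categories: background, tumor-only,
lymphocyte-only, or co-positive (tumor AND lymphocyte).  Percent
infiltration is the fraction of tumor-positive cells that are also
lymphocyte-positive, expressed as a percentage — the slide-level TIL
infiltrate measure used throughout the survival layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import AlignmentError, ParameterError, UndefinedFeatureError
from .grids import HeatmapGrid, LatticePair

__all__ = [
    "CATEGORY_BACKGROUND",
    "CATEGORY_TUMOR",
    "CATEGORY_LYMPH",
    "CATEGORY_BOTH",
    "CompositeMap",
    "InfiltrationSummary",
    "compose_map",
    "percent_infiltration",
    "assign_til_class",
    "render_four_panel",
]

CATEGORY_BACKGROUND = 0
CATEGORY_TUMOR = 1
CATEGORY_LYMPH = 2
CATEGORY_BOTH = 3


@dataclass
class CompositeMap:
    """Per-cell tumor/lymphocyte flags on the common fine lattice."""

    tumor: np.ndarray
    lymph: np.ndarray
    cell_size_um: float
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.tumor = np.asarray(self.tumor, dtype=bool)
        self.lymph = np.asarray(self.lymph, dtype=bool)
        if self.tumor.shape != self.lymph.shape:
            raise AlignmentError("tumor and lymph grids must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tumor.shape

    def categories(self) -> np.ndarray:
        """Category code per cell; the four codes partition all cells."""
        return (
            self.tumor.astype(np.uint8) * CATEGORY_TUMOR
            + self.lymph.astype(np.uint8) * CATEGORY_LYMPH
        )


@dataclass
class InfiltrationSummary:
    """Slide-level TIL infiltration: co-positive over tumor cell counts."""

    n_tumor_cells: int
    n_co_positive_cells: int
    percent_infiltration: float
    til_class: str | None = None  # "High"/"Low", assigned at cohort level


def compose_map(pair: LatticePair) -> CompositeMap:
    """Overlay an aligned tumor/lymphocyte pair into a Tumor-TIL map."""
    return CompositeMap(
        pair.tumor.values.copy(),
        pair.lymph.values.copy(),
        pair.cell_size_um,
        pair.tumor.slide_id,
    )


def percent_infiltration(cmap: CompositeMap) -> InfiltrationSummary:
    """TIL infiltrate percentage: 100 * co-positive cells / tumor cells.

    Raises
    ------
    UndefinedFeatureError
        If the map contains no tumor-positive cells; the slide must be
        flagged rather than silently scored 0.
    """
    n_tumor = int(cmap.tumor.sum())
    if n_tumor == 0:
        raise UndefinedFeatureError(
            f"slide {cmap.slide_id!r}: no tumor-positive cells; "
            "percent infiltration undefined"
        )
    n_co = int((cmap.tumor & cmap.lymph).sum())
    return InfiltrationSummary(n_tumor, n_co, 100.0 * n_co / n_tumor)


def assign_til_class(
    values: "list[float] | np.ndarray", center: str = "mean"
) -> list[str]:
    """Split a cohort of infiltration percentages into High/Low TIL classes.

    A slide is High iff its value strictly exceeds the cohort center
    statistic (mean by default, median supported); ties go Low.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ParameterError("TIL class needs at least two cohort values")
    if not np.all(np.isfinite(arr)):
        raise ParameterError("TIL class requires finite infiltration values")
    if center == "mean":
        c = float(arr.mean())
    elif center == "median":
        c = float(np.median(arr))
    else:
        raise ParameterError(f"unknown center statistic {center!r}")
    return ["High" if v > c else "Low" for v in arr]


# Tumor-TIL map palette: tumor yellow, lymphocytes red (red overrides yellow
# in co-positive cells for lymphocyte visibility), other tissue gray.
_RGB = {
    CATEGORY_BACKGROUND: (180, 180, 180),
    CATEGORY_TUMOR: (255, 215, 0),
    CATEGORY_LYMPH: (200, 0, 0),
    CATEGORY_BOTH: (200, 0, 0),
}


def tumortil_rgb(cmap: CompositeMap) -> np.ndarray:
    """Render a composite map to an RGB uint8 array using the map palette."""
    cats = cmap.categories()
    rgb = np.zeros(cats.shape + (3,), dtype=np.uint8)
    for code, color in _RGB.items():
        rgb[cats == code] = color
    return rgb


def render_four_panel(
    tumor_heatmap: HeatmapGrid,
    lymph_heatmap: HeatmapGrid,
    cmap: CompositeMap,
    out: str | Path,
    thumbnail: np.ndarray | None = None,
) -> Path:
    """Write the four-panel composite PNG for one slide.

    Panels: low-resolution slide thumbnail (a neutral placeholder when no
    image is supplied), the two probability heatmaps on a blue-to-red
    scale, and the Tumor-TIL map.
    """
    if not (tumor_heatmap.slide_id == lymph_heatmap.slide_id == cmap.slide_id):
        raise AlignmentError("four-panel inputs must share a slide id")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 4, figsize=(16, 4.2))
    if thumbnail is None:
        thumbnail = np.full((64, 64), 0.92)
    axes[0].imshow(thumbnail, cmap="gray", vmin=0, vmax=1)
    axes[0].set_title("H&E (thumbnail)")
    for ax, grid, title in (
        (axes[1], tumor_heatmap, "Tumor probability"),
        (axes[2], lymph_heatmap, "Lymphocyte probability"),
    ):
        im = ax.imshow(grid.values, cmap="coolwarm", vmin=0, vmax=1,
                       interpolation="nearest")
        ax.set_title(title)
        fig.colorbar(im, ax=ax, fraction=0.046)
    axes[3].imshow(tumortil_rgb(cmap), interpolation="nearest")
    axes[3].set_title("Tumor-TIL map")
    for ax in axes:
        ax.set_xticks([])
        ax.set_yticks([])
    fig.suptitle(cmap.slide_id)
    out = Path(out)
    try:
        fig.savefig(out, dpi=120, bbox_inches="tight")
    except OSError as exc:
        raise OSError(f"cannot write four-panel composite to {out}") from exc
    finally:
        plt.close(fig)
    return out
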