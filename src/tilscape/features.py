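"""Spatial-ecology scoring of Tumor-TIL maps.

Five features describe how lymphocytes distribute with respect to the tumor,
using vocabulary adapted from ecology:

* **intratumoral strength** (0-3): graded abundance of TIL-positive cells
  inside the tumor region, from absent (0) to strong diffuse infiltration (3).
* **intratumoral deserts** (0/1): 1 when significant confluent tumor regions
  completely clear of TIL infiltrate cover at least 25% of the tumor area.
* **intratumoral forests** (0/1): 1 when confluent groups of TILs span at
  least 10% of the tumor area.
* **peritumoral strength** (0-3): graded TIL abundance in a band around the
  invasive tumor boundary.
* **tertiary lymphoid aggregates** (0/1): 1 when multifocal TIL clusters
  exist beyond the peritumoral region.

Each graded score maps to a binary high-risk indicator (low intratumoral
0-1, deserts present, forests absent, low peritumoral 0-1, aggregates
absent); patients with two or more high-risk features form the high-risk
group.  Aggregates are excluded from the default active indicator set
because their interrater agreement fell below the screening cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .compose import CompositeMap
from .errors import ParameterError, UndefinedFeatureError

__all__ = [
    "MorphologyConfig",
    "FeatureScores",
    "HighRiskProfile",
    "FEATURE_NAMES",
    "INDICATOR_NAMES",
    "DEFAULT_ACTIVE_INDICATORS",
    "connected_components",
    "score_deserts",
    "score_forests",
    "score_intratumoral_strength",
    "peritumoral_band",
    "score_peritumoral_strength",
    "score_aggregates",
    "score_all",
    "high_risk_profile",
]

FEATURE_NAMES = (
    "intratumoral_strength",
    "deserts",
    "forests",
    "peritumoral_strength",
    "aggregates",
)

#: Number of ordinal categories per feature (strengths 0-3, binaries 0-1).
FEATURE_CATEGORIES = {
    "intratumoral_strength": 4,
    "deserts": 2,
    "forests": 2,
    "peritumoral_strength": 3 + 1,
    "aggregates": 2,
}

INDICATOR_NAMES = (
    "low_intratumoral",
    "deserts_present",
    "forests_absent",
    "low_peritumoral",
    "aggregates_absent",
)

#: Aggregates are screened out of high-risk scoring by default (low
#: interrater agreement); the other four indicators are active.
DEFAULT_ACTIVE_INDICATORS = frozenset(INDICATOR_NAMES[:4])


@dataclass(frozen=True)
class MorphologyConfig:
    """Tunable morphology parameters behind the five scoring rules.

    The two area thresholds (desert 25%, forest 10% of tumor area) are the
    published scoring criteria.  The remaining knobs make the qualitative
    parts of the rules operational and are design parameters: minimum
    component sizes exclude speckle, the strength ladder turns weak/
    moderate/strong into fractions, and the band width defines the
    peritumoral region.

    Attributes
    ----------
    connectivity
        4 or 8 neighborhood for confluent components (4 by default —
        conservative confluence).
    desert_min_component_frac
        A TIL-free tumor component qualifies as part of a desert only if it
        covers at least this fraction of tumor area (default 1%).
    desert_area_frac_threshold
        Desert score is 1 iff qualifying TIL-free area >= this fraction of
        tumor area (default 0.25, the published criterion).
    forest_min_component_frac
        Minimum confluent TIL component size, as fraction of tumor area,
        to count toward forests (default 2%; the published rule tolerates
        "1-2 small confluent groups" at score 0 without quantifying small).
    forest_area_frac_threshold
        Forest score is 1 iff qualifying confluent TIL area >= this
        fraction of tumor area (default 0.10, the published criterion).
    band_width_cells
        Peritumoral band depth in fine-lattice cells beyond the tumor mask
        (default 2 cells = 25 µm at the 12.5 µm pitch); 4 cells (= one
        50 µm lymphocyte patch) is a reasonable alternative preset.
    strength_cutoffs
        Ascending fractions grading strength 0-3: the score is the number
        of cutoffs the infiltration fraction strictly exceeds.  Defaults
        (0, 0.05, 0.15): zero infiltration scores 0, up to 5% scores 1,
        5-15% scores 2, above 15% scores 3.
    aggregate_min_cells
        Minimum size (cells) of a distal lymphoid cluster (default 5).
    aggregate_multifocal_min
        Minimum number of qualifying distal clusters for "multifocal"
        (default 2).
    dilation_connectivity
        Neighborhood for the band dilation metric: 8 (chebyshev) or
        4 (manhattan).  Default 8.
    """

    connectivity: int = 4
    desert_min_component_frac: float = 0.01
    desert_area_frac_threshold: float = 0.25
    forest_min_component_frac: float = 0.02
    forest_area_frac_threshold: float = 0.10
    band_width_cells: int = 2
    strength_cutoffs: tuple[float, float, float] = (0.0, 0.05, 0.15)
    aggregate_min_cells: int = 5
    aggregate_multifocal_min: int = 2
    dilation_connectivity: int = 8

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ParameterError("connectivity must be 4 or 8")
        if self.dilation_connectivity not in (4, 8):
            raise ParameterError("dilation_connectivity must be 4 or 8")
        for name in (
            "desert_min_component_frac",
            "desert_area_frac_threshold",
            "forest_min_component_frac",
            "forest_area_frac_threshold",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ParameterError(f"{name} must lie in (0, 1)")
        if list(self.strength_cutoffs) != sorted(set(self.strength_cutoffs)):
            raise ParameterError("strength_cutoffs must be strictly ascending")
        if len(self.strength_cutoffs) != 3:
            raise ParameterError("strength_cutoffs needs three fractions")
        if self.band_width_cells < 1 or self.aggregate_min_cells < 1:
            raise ParameterError("cell counts must be >= 1")
        if self.aggregate_multifocal_min < 1:
            raise ParameterError("aggregate_multifocal_min must be >= 1")


DEFAULT_CONFIG = MorphologyConfig()


@dataclass
class FeatureScores:
    """The five spatial-feature scores for one slide (or an exclusion)."""

    intratumoral_strength: int | None = None
    deserts: int | None = None
    forests: int | None = None
    peritumoral_strength: int | None = None
    aggregates: int | None = None
    excluded: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if self.excluded:
            return
        for name, hi in (
            ("intratumoral_strength", 3),
            ("deserts", 1),
            ("forests", 1),
            ("peritumoral_strength", 3),
            ("aggregates", 1),
        ):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= hi:
                raise ParameterError(f"{name}={v} outside 0..{hi}")

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES} | {
            "excluded": self.excluded,
            "reason": self.reason,
        }


@dataclass
class HighRiskProfile:
    """Which high-risk indicators fire for one slide, and the group call."""

    indicators: frozenset[str]
    count: int
    group: str  # "high-risk" | "low-risk"


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)


def connected_components(
    grid: np.ndarray, connectivity: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Label maximal connected True-regions; returns (labels, sizes).

    Labels run 1..k; ``sizes[i]`` is the cell count of component ``i + 1``.
    """
    if connectivity not in (4, 8):
        raise ParameterError("connectivity must be 4 or 8")
    grid = np.asarray(grid, dtype=bool)
    labels, k = ndimage.label(grid, structure=_structure(connectivity))
    sizes = np.bincount(labels.ravel(), minlength=k + 1)[1:]
    return labels, sizes


def _tumor_area(cmap: CompositeMap, feature: str) -> int:
    n = int(cmap.tumor.sum())
    if n == 0:
        raise UndefinedFeatureError(
            f"slide {cmap.slide_id!r}: empty tumor mask; {feature} undefined"
        )
    return n


def score_deserts(
    cmap: CompositeMap, cfg: MorphologyConfig = DEFAULT_CONFIG
) -> int:
    """Immune-cold desert call: 1 iff significant confluent TIL-free tumor
    regions cover >= 25% of tumor area (default thresholds).

    Components of tumor AND NOT lymphocyte cells qualify when at least
    ``desert_min_component_frac`` of tumor area; their areas sum.
    """
    area = _tumor_area(cmap, "deserts")
    _, sizes = connected_components(cmap.tumor & ~cmap.lymph, cfg.connectivity)
    qualifying = sizes[sizes >= cfg.desert_min_component_frac * area]
    return int(qualifying.sum() >= cfg.desert_area_frac_threshold * area)


def score_forests(
    cmap: CompositeMap, cfg: MorphologyConfig = DEFAULT_CONFIG
) -> int:
    """TIL forest call: 1 iff confluent groups of intratumoral TILs span
    >= 10% of tumor area (default thresholds)."""
    area = _tumor_area(cmap, "forests")
    _, sizes = connected_components(cmap.tumor & cmap.lymph, cfg.connectivity)
    qualifying = sizes[sizes >= cfg.forest_min_component_frac * area]
    return int(qualifying.sum() >= cfg.forest_area_frac_threshold * area)


def _grade(fraction: float, cutoffs: tuple[float, ...]) -> int:
    return int(sum(fraction > c for c in cutoffs))


def score_intratumoral_strength(
    cmap: CompositeMap, cfg: MorphologyConfig = DEFAULT_CONFIG
) -> int:
    """Grade intratumoral TIL abundance 0-3.

    Score 0 means no TIL-positive cells inside the tumor region; otherwise
    the infiltration fraction is graded by the configured ladder.
    """
    area = _tumor_area(cmap, "intratumoral strength")
    frac = (cmap.tumor & cmap.lymph).sum() / area
    return _grade(frac, cfg.strength_cutoffs)


def peritumoral_band(
    cmap: CompositeMap, cfg: MorphologyConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Band of cells within ``band_width_cells`` of the tumor, outside it.

    Distances are chebyshev for dilation connectivity 8, manhattan for 4;
    implemented as a chamfer distance transform from the tumor mask.
    """
    _tumor_area(cmap, "peritumoral band")
    metric = "chessboard" if cfg.dilation_connectivity == 8 else "taxicab"
    dist = ndimage.distance_transform_cdt(~cmap.tumor, metric=metric)
    return (dist > 0) & (dist <= cfg.band_width_cells)


def score_peritumoral_strength(
    cmap: CompositeMap, cfg: MorphologyConfig = DEFAULT_CONFIG
) -> int:
    """Grade TIL abundance in the invasive-boundary band 0-3.

    The fraction of band cells that are lymphocyte-positive is graded by
    the same ladder as intratumoral strength.

    Raises
    ------
    UndefinedFeatureError
        If the band is empty (tumor fills the whole grid).
    """
    band = peritumoral_band(cmap, cfg)
    n_band = int(band.sum())
    if n_band == 0:
        raise UndefinedFeatureError(
            f"slide {cmap.slide_id!r}: empty peritumoral band; "
            "peritumoral strength undefined"
        )
    frac = (band & cmap.lymph).sum() / n_band
    return _grade(frac, cfg.strength_cutoffs)


def score_aggregates(
    cmap: CompositeMap, cfg: MorphologyConfig = DEFAULT_CONFIG
) -> int:
    """Tertiary lymphoid aggregate call: 1 iff multifocal TIL clusters
    exist beyond the peritumoral region.

    A lymphocyte component qualifies when it lies entirely outside
    tumor + band and has at least ``aggregate_min_cells`` cells; the call
    is 1 when at least ``aggregate_multifocal_min`` components qualify.
    """
    try:
        band = peritumoral_band(cmap, cfg)
    except UndefinedFeatureError:
        band = np.zeros(cmap.shape, dtype=bool)
    near = cmap.tumor | band
    labels, sizes = connected_components(cmap.lymph, cfg.connectivity)
    if labels.max() == 0:
        return 0
    touches_near = np.zeros(sizes.size + 1, dtype=bool)
    touches_near[np.unique(labels[near & (labels > 0)])] = True
    qualifying = 0
    for lab in range(1, sizes.size + 1):
        if not touches_near[lab] and sizes[lab - 1] >= cfg.aggregate_min_cells:
            qualifying += 1
    return int(qualifying >= cfg.aggregate_multifocal_min)


def score_all(
    cmap: CompositeMap, cfg: MorphologyConfig = DEFAULT_CONFIG
) -> FeatureScores:
    """Score all five spatial features for one map.

    A map on which any feature is undefined (empty tumor mask, empty
    peritumoral band) is excluded with a reason instead of partially
    scored.
    """
    try:
        return FeatureScores(
            intratumoral_strength=score_intratumoral_strength(cmap, cfg),
            deserts=score_deserts(cmap, cfg),
            forests=score_forests(cmap, cfg),
            peritumoral_strength=score_peritumoral_strength(cmap, cfg),
            aggregates=score_aggregates(cmap, cfg),
        )
    except UndefinedFeatureError as exc:
        return FeatureScores(excluded=True, reason=str(exc))


def high_risk_profile(
    scores: FeatureScores,
    active: "frozenset[str] | set[str]" = DEFAULT_ACTIVE_INDICATORS,
) -> HighRiskProfile:
    """Map graded scores to high-risk indicators and the >= 2 group rule.

    Indicators: low intratumoral TILs (strength 0 or 1), presence of
    deserts (1), absence of forests (0), low peritumoral TILs (0 or 1),
    and — only when activated — absence of aggregates (0).  A patient is
    high-risk iff at least two active indicators fire.
    """
    if scores.excluded:
        raise UndefinedFeatureError(
            f"cannot risk-profile excluded scores ({scores.reason})"
        )
    unknown = set(active) - set(INDICATOR_NAMES)
    if unknown:
        raise ParameterError(f"unknown indicators: {sorted(unknown)}")
    fired = set()
    if scores.intratumoral_strength <= 1:
        fired.add("low_intratumoral")
    if scores.deserts == 1:
        fired.add("deserts_present")
    if scores.forests == 0:
        fired.add("forests_absent")
    if scores.peritumoral_strength <= 1:
        fired.add("low_peritumoral")
    if scores.aggregates == 0:
        fired.add("aggregates_absent")
    fired &= set(active)
    count = len(fired)
    return HighRiskProfile(
        indicators=frozenset(fired),
        count=count,
        group="high-risk" if count >= 2 else "low-risk",
    )
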