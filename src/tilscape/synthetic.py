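"""Synthetic paired heatmaps with planted spatial phenotypes, and synthetic
cohorts with planted hazards.

The generator emulates the statistical and spatial structure of real
patch-classifier output — a connected tumor region on the coarse (87.5 µm)
tumor lattice, lymphocyte patterns on the finer (50 µm) lymphocyte lattice,
and per-patch probabilities concentrated near 0 and 1 like confident CNN
maps — without attempting to mimic H&E texture or classifier failure modes.

Phenotypes mirror the spatial-ecology taxonomy: ``cold`` (no TILs),
``diffuse`` (scattered intratumoral TILs at a controllable density),
``forest`` (one confluent intratumoral TIL block), ``desert`` (a contiguous
TIL-free tumor region, the remainder infiltrated), ``peritumoral_ring``
(TILs concentrated at the invasive boundary), ``distal_aggregates``
(multifocal TIL clusters beyond the peritumoral band), and ``mixed``.

Probability noise: positives are drawn from 1 − Beta(2, 8)/2 (support
(0.5, 1], mean 0.9) and negatives from Beta(2, 8)/2 (support [0, 0.5),
mean 0.1).  The ``jitter`` parameter adds label flips with probability
``max(0, jitter − 0.2)``: at the default jitter of 0.2 and below,
binarization at 0.5 recovers the planted boolean pattern exactly (the
guaranteed margin); larger jitter stresses the pipeline.

Cohorts: event times are exponential (Weibull optional) with patient rate
baseline × exp(linear predictor); censoring is uniform over the follow-up
window; times are rounded up to whole days, so ties occur as they do in
real day-resolution registries.  All generators are pure functions of
their spec: the seed fixes every draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .compose import CompositeMap, compose_map, percent_infiltration
from .consensus import RaterPanel
from .errors import GenerationError, ParameterError
from .features import (
    DEFAULT_CONFIG,
    FEATURE_CATEGORIES,
    FEATURE_NAMES,
    FeatureScores,
    MorphologyConfig,
    high_risk_profile,
    score_all,
)
from .grids import (
    LYMPH_PATCH_UM,
    TUMOR_PATCH_UM,
    BinaryGrid,
    HeatmapGrid,
    resample_to_common_lattice,
)
from .survival import PatientRecord

__all__ = [
    "PHENOTYPES",
    "PhenotypeSpec",
    "CohortSpec",
    "generate_tumor_mask",
    "plant_phenotype",
    "simulate_raters",
    "simulate_cohort",
    "GUARANTEED_JITTER",
]

PHENOTYPES = (
    "cold",
    "diffuse",
    "forest",
    "desert",
    "peritumoral_ring",
    "distal_aggregates",
    "mixed",
)

#: Largest jitter at which binarization is guaranteed to recover the
#: planted boolean pattern exactly (no label flips).
GUARANTEED_JITTER = 0.2


@dataclass(frozen=True)
class PhenotypeSpec:
    """Parameters for planting one ground-truth spatial phenotype.

    ``tumor_shape`` is the tumor-model grid (87.5 µm patches); the
    lymphocyte grid is derived from the shared physical extent at 50 µm.
    Identical specs produce identical output (the seed fixes all draws).
    """

    phenotype: str = "diffuse"
    tumor_shape: tuple[int, int] = (24, 24)
    tumor_patch_um: float = TUMOR_PATCH_UM
    lymph_patch_um: float = LYMPH_PATCH_UM
    blob_count: int = 3
    radius_frac_range: tuple[float, float] = (0.18, 0.30)
    diffuse_density: float = 0.5
    desert_frac: float = 0.30
    forest_frac: float = 0.12
    band_til_frac: float = 0.9
    n_aggregates: int = 3
    aggregate_radius_cells: int = 2
    jitter: float = GUARANTEED_JITTER
    seed: int = 0
    slide_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ParameterError(f"unknown phenotype {self.phenotype!r}")
        for name in ("diffuse_density", "desert_frac", "forest_frac",
                     "band_til_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.jitter < 0:
            raise ParameterError("jitter must be >= 0")
        if self.desert_frac > 0.95 and self.phenotype in ("desert", "mixed"):
            raise ParameterError("desert_frac too large for a scorable tumor")

    @property
    def lymph_shape(self) -> tuple[int, int]:
        return tuple(
            int(round(n * self.tumor_patch_um / self.lymph_patch_um))
            for n in self.tumor_shape
        )


@dataclass(frozen=True)
class CohortSpec:
    """Parameters for a synthetic PFI cohort with planted hazards.

    ``coefficients`` maps planted covariates to log hazard ratios; the
    supported keys are ``high_risk`` (the >= 2 high-risk-feature group
    indicator) and ``infiltration_per_sd`` (percent infiltration scaled by
    its cohort SD).  Baseline rate and censoring window defaults are
    calibrated so the default spec (half the cohort high-risk at hazard
    ratio 2) yields roughly 40% events.
    """

    n: int = 400
    pam50_probs: dict = field(
        default_factory=lambda: {
            "LumA": 0.51, "Basal": 0.23, "LumB": 0.18, "Her2": 0.08,
        }
    )
    er_probs: dict = field(
        default_factory=lambda: {"Positive": 0.77, "Negative": 0.23}
    )
    stage_probs: dict = field(
        default_factory=lambda: {"I": 0.39, "II": 0.46, "III": 0.13, "IV": 0.02}
    )
    baseline_rate: float = 0.8 / 3000.0  # events per day
    coefficients: dict = field(
        default_factory=lambda: {"high_risk": math.log(2.0)}
    )
    high_risk_prob: float = 0.5
    censoring_days: float = 3000.0
    time_distribution: str = "exponential"
    weibull_shape: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError("cohort needs n >= 2")
        if self.baseline_rate <= 0 or self.censoring_days <= 0:
            raise ParameterError("rates and windows must be positive")
        for name in ("pam50_probs", "er_probs", "stage_probs"):
            probs = getattr(self, name)
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ParameterError(f"{name} must sum to 1")
        if self.time_distribution not in ("exponential", "weibull"):
            raise ParameterError("time_distribution must be exponential|weibull")
        if self.weibull_shape <= 0:
            raise ParameterError("weibull_shape must be positive")


def generate_tumor_mask(spec: PhenotypeSpec) -> BinaryGrid:
    """Connected tumor blob on the tumor lattice: a seeded union of discs.

    The first disc sits near the grid center; each later disc's center is
    drawn inside an earlier disc, keeping the union connected.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.tumor_shape
    rmin = int(round(spec.radius_frac_range[0] * min(rows, cols)))
    rmax = int(round(spec.radius_frac_range[1] * min(rows, cols)))
    rmin = max(rmin, 1)
    rmax = max(rmax, rmin)
    yy, xx = np.mgrid[0:rows, 0:cols]
    mask = np.zeros((rows, cols), dtype=bool)
    centers: list[tuple[float, float, float]] = []
    for b in range(spec.blob_count):
        radius = float(rng.integers(rmin, rmax + 1))
        if b == 0:
            cy = rows / 2 + rng.uniform(-rows / 8, rows / 8)
            cx = cols / 2 + rng.uniform(-cols / 8, cols / 8)
        else:
            py, px, pr = centers[rng.integers(0, len(centers))]
            theta = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, pr)
            cy, cx = py + rad * np.sin(theta), px + rad * np.cos(theta)
        centers.append((cy, cx, radius))
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    if not mask.any():
        raise GenerationError("tumor geometry produced an empty mask")
    return BinaryGrid(mask, spec.tumor_patch_um, spec.slide_id)


def _upsample_to_lymph(spec: PhenotypeSpec, tumor_mask: np.ndarray) -> np.ndarray:
    """Tumor-region proxy on the lymphocyte lattice (cell-center lookup)."""
    lr, lc = spec.lymph_shape
    ratio = spec.lymph_patch_um / spec.tumor_patch_um
    rows = np.minimum(
        ((np.arange(lr) + 0.5) * ratio).astype(int), tumor_mask.shape[0] - 1
    )
    cols = np.minimum(
        ((np.arange(lc) + 0.5) * ratio).astype(int), tumor_mask.shape[1] - 1
    )
    return tumor_mask[np.ix_(rows, cols)]


def _grow_region(
    rng: np.random.Generator, allowed: np.ndarray, target_cells: int,
    start: tuple[int, int] | None = None,
) -> np.ndarray:
    """Grow a 4-connected region of ~target_cells cells inside ``allowed``."""
    coords = np.argwhere(allowed)
    if coords.size == 0 or target_cells < 1:
        return np.zeros_like(allowed)
    if start is None:
        start = tuple(coords[rng.integers(0, len(coords))])
    region = np.zeros_like(allowed)
    frontier = [start]
    region[start] = True
    count = 1
    while frontier and count < target_cells:
        idx = rng.integers(0, len(frontier))
        frontier[idx], frontier[-1] = frontier[-1], frontier[idx]
        y, x = frontier.pop()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ny, nx = y + dy, x + dx
            if (
                0 <= ny < allowed.shape[0]
                and 0 <= nx < allowed.shape[1]
                and allowed[ny, nx]
                and not region[ny, nx]
            ):
                region[ny, nx] = True
                frontier.append((ny, nx))
                count += 1
                if count >= target_cells:
                    break
    return region


def _fine_tumor_mask(spec: PhenotypeSpec, tumor: BinaryGrid) -> np.ndarray:
    """Tumor mask replicated onto the common fine lattice."""
    empty_lymph = BinaryGrid(
        np.zeros(spec.lymph_shape, dtype=bool), spec.lymph_patch_um,
        spec.slide_id,
    )
    return resample_to_common_lattice(tumor, empty_lymph).tumor.values


def _interior_proxy(
    spec: PhenotypeSpec, fine_tumor: np.ndarray
) -> tuple[np.ndarray, int]:
    """Lymphocyte cells whose full fine footprint is tumor, plus the number
    of fine cells one lymphocyte cell covers."""
    from .grids import _gcd_um

    pitch = _gcd_um(spec.tumor_patch_um, spec.lymph_patch_um)
    per_side = int(round(spec.lymph_patch_um / pitch))
    lr, lc = spec.lymph_shape
    interior = np.zeros((lr, lc), dtype=bool)
    fr, fc = fine_tumor.shape
    for i in range(lr):
        r0, r1 = i * per_side, (i + 1) * per_side
        if r1 > fr:
            break
        for j in range(lc):
            c0, c1 = j * per_side, (j + 1) * per_side
            if c1 > fc:
                break
            interior[i, j] = fine_tumor[r0:r1, c0:c1].all()
    return interior, per_side * per_side


def _plant_lymph_pattern(
    spec: PhenotypeSpec,
    rng: np.random.Generator,
    tumor_proxy: np.ndarray,
    fine_tumor: np.ndarray,
    interior: np.ndarray,
    cells_per_patch: int,
) -> np.ndarray:
    """Boolean lymphocyte pattern on the lymphocyte lattice.

    Desert and forest targets are sized against the fine-lattice tumor
    area and grown inside the interior proxy (cells fully covered by
    tumor), so planted area fractions survive lattice alignment intact.
    """
    from scipy import ndimage

    lymph = np.zeros_like(tumor_proxy)
    if not tumor_proxy.any():
        raise GenerationError("tumor proxy is empty on the lymphocyte lattice")
    n_fine = int(fine_tumor.sum())

    def scatter(where: np.ndarray, density: float) -> None:
        cells = np.argwhere(where)
        k = int(round(density * len(cells)))
        if k > 0:
            pick = rng.choice(len(cells), size=k, replace=False)
            lymph[tuple(cells[pick].T)] = True

    def grow(allowed: np.ndarray, frac: float, label: str) -> np.ndarray:
        target = math.ceil(frac * n_fine / cells_per_patch)
        region = _grow_region(rng, allowed, target)
        if region.sum() < target:  # interior too tight; spill into proxy
            extra = _grow_region_from(
                rng, tumor_proxy & ~region, region, target - int(region.sum())
            )
            region |= extra
        if region.sum() < target:
            raise GenerationError(
                f"cannot plant {label} covering {frac:.0%} of tumor area"
            )
        return region

    ring = ndimage.binary_dilation(
        tumor_proxy, structure=np.ones((3, 3), bool), iterations=1
    ) & ~tumor_proxy
    far = ~ndimage.binary_dilation(
        tumor_proxy, structure=np.ones((3, 3), bool), iterations=5
    )

    pheno = spec.phenotype
    if pheno == "cold":
        pass
    elif pheno == "diffuse":
        scatter(tumor_proxy, spec.diffuse_density)
    elif pheno == "forest":
        lymph |= grow(interior, spec.forest_frac, "a TIL forest")
        scatter(tumor_proxy & ~lymph, 0.03)
    elif pheno == "desert":
        hole = grow(interior, spec.desert_frac, "a TIL desert")
        scatter(tumor_proxy & ~hole, 0.6)
    elif pheno == "peritumoral_ring":
        scatter(ring, spec.band_til_frac)
        scatter(tumor_proxy, 0.02)
    elif pheno == "distal_aggregates":
        _place_aggregates(spec, rng, lymph, far)
        scatter(tumor_proxy, 0.03)
    elif pheno == "mixed":
        hole = grow(interior, spec.desert_frac, "a TIL desert")
        lymph |= grow(interior & ~hole, spec.forest_frac, "a TIL forest")
        scatter(ring, spec.band_til_frac)
        _place_aggregates(spec, rng, lymph, far)
    return lymph


def _grow_region_from(
    rng: np.random.Generator,
    allowed: np.ndarray,
    seed_region: np.ndarray,
    extra_cells: int,
) -> np.ndarray:
    """Grow ``extra_cells`` more cells into ``allowed`` from an existing
    region's boundary (used when the interior proxy is too tight)."""
    from scipy import ndimage

    region = np.zeros_like(allowed)
    frontier = list(
        map(
            tuple,
            np.argwhere(
                ndimage.binary_dilation(seed_region) & allowed
            ),
        )
    )
    count = 0
    while frontier and count < extra_cells:
        idx = rng.integers(0, len(frontier))
        frontier[idx], frontier[-1] = frontier[-1], frontier[idx]
        y, x = frontier.pop()
        if region[y, x]:
            continue
        region[y, x] = True
        count += 1
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ny, nx = y + dy, x + dx
            if (
                0 <= ny < allowed.shape[0]
                and 0 <= nx < allowed.shape[1]
                and allowed[ny, nx]
                and not region[ny, nx]
            ):
                frontier.append((ny, nx))
    return region


def _place_aggregates(
    spec: PhenotypeSpec, rng: np.random.Generator, lymph: np.ndarray,
    far: np.ndarray,
) -> None:
    """Stamp compact discs of TILs in the far field (beyond the band)."""
    yy, xx = np.mgrid[0 : lymph.shape[0], 0 : lymph.shape[1]]
    sites = np.argwhere(far)
    if len(sites) == 0:
        raise GenerationError("no far-field room for distal aggregates")
    placed = 0
    used = np.zeros_like(far)
    for _ in range(200):
        if placed >= spec.n_aggregates:
            break
        cy, cx = sites[rng.integers(0, len(sites))]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.aggregate_radius_cells**2
        # keep aggregates separated so they stay multifocal
        halo = (yy - cy) ** 2 + (xx - cx) ** 2 <= (
            spec.aggregate_radius_cells + 2
        ) ** 2
        if (disc & ~far).any() or (halo & used).any():
            continue
        lymph |= disc
        used |= halo
        placed += 1
    if placed < min(spec.n_aggregates, 2):
        raise GenerationError("could not place multifocal distal aggregates")


def _probabilities(
    rng: np.random.Generator, pattern: np.ndarray, jitter: float
) -> np.ndarray:
    """CNN-like confidence map for a boolean pattern.

    Negatives live in [0, 0.5), positives in (0.5, 1]; flips occur with
    probability max(0, jitter - GUARANTEED_JITTER).
    """
    flip_p = max(0.0, jitter - GUARANTEED_JITTER)
    effective = pattern.copy()
    if flip_p > 0:
        flips = rng.random(pattern.shape) < flip_p
        effective ^= flips
    lo = 0.5 * rng.beta(2.0, 8.0, size=pattern.shape)
    values = np.where(effective, 1.0 - lo, lo)
    return values


def _planted_patterns(
    spec: PhenotypeSpec,
) -> tuple[BinaryGrid, np.ndarray, np.random.Generator]:
    """Shared construction: tumor grid, lymphocyte pattern, and the rng
    positioned for probability sampling."""
    tumor = generate_tumor_mask(spec)
    rng = np.random.default_rng(spec.seed + 1)
    proxy = _upsample_to_lymph(spec, tumor.values)
    fine_tumor = _fine_tumor_mask(spec, tumor)
    interior, cells_per_patch = _interior_proxy(spec, fine_tumor)
    lymph_pattern = _plant_lymph_pattern(
        spec, rng, proxy, fine_tumor, interior, cells_per_patch
    )
    return tumor, lymph_pattern, rng


def planted_composite(spec: PhenotypeSpec) -> CompositeMap:
    """Noiseless composite map of the planted pattern on the fine lattice."""
    tumor, lymph_pattern, _ = _planted_patterns(spec)
    pair = resample_to_common_lattice(
        tumor, BinaryGrid(lymph_pattern, spec.lymph_patch_um, spec.slide_id)
    )
    return compose_map(pair)


def plant_phenotype(
    spec: PhenotypeSpec, cfg: MorphologyConfig = DEFAULT_CONFIG
) -> tuple[HeatmapGrid, HeatmapGrid, FeatureScores]:
    """Paired probability heatmaps plus ground-truth feature scores.

    The ground truth is the score of the noiseless planted pattern pushed
    through the same compose-and-score path, i.e. what a perfect
    classifier would yield for this geometry; at jitter within the
    guaranteed margin, binarizing the returned probability grids
    reproduces the planted pattern exactly.
    """
    tumor, lymph_pattern, rng = _planted_patterns(spec)
    pair = resample_to_common_lattice(
        tumor, BinaryGrid(lymph_pattern, spec.lymph_patch_um, spec.slide_id)
    )
    truth = score_all(compose_map(pair), cfg)

    tumor_probs = _probabilities(rng, tumor.values, spec.jitter)
    lymph_probs = _probabilities(rng, lymph_pattern, spec.jitter)
    return (
        HeatmapGrid(tumor_probs, spec.tumor_patch_um, spec.slide_id),
        HeatmapGrid(lymph_probs, spec.lymph_patch_um, spec.slide_id),
        truth,
    )


def phenotype_spectrum_specs(
    n: int, seed: int = 0
) -> "list[PhenotypeSpec]":
    """Slide specs spanning the phenotype spectrum of a screening cohort.

    Mixture: 10% immune-cold, 50% sparse diffuse infiltration (density
    uniform up to 0.30), 15% hot diffuse (0.75-0.95, brisk infiltrates
    without deserts), 10% forests, 10% deserts, 5% peritumoral rings —
    a spread that exercises every strength grade and both desert states.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        u = rng.random()
        slide_seed = seed * 100_000 + i
        if u < 0.10:
            spec = PhenotypeSpec(phenotype="cold", seed=slide_seed)
        elif u < 0.60:
            spec = PhenotypeSpec(
                phenotype="diffuse",
                diffuse_density=float(rng.uniform(0.0, 0.30)),
                seed=slide_seed,
            )
        elif u < 0.75:
            spec = PhenotypeSpec(
                phenotype="diffuse",
                diffuse_density=float(rng.uniform(0.75, 0.95)),
                seed=slide_seed,
            )
        elif u < 0.85:
            spec = PhenotypeSpec(phenotype="forest", seed=slide_seed)
        elif u < 0.95:
            spec = PhenotypeSpec(phenotype="desert", seed=slide_seed)
        else:
            spec = PhenotypeSpec(phenotype="peritumoral_ring", seed=slide_seed)
        specs.append(replace(spec, slide_id=f"syn_{i:04d}"))
    return specs


_ADJACENT = {
    feature: {
        v: [a for a in (v - 1, v + 1) if 0 <= a < k]
        for v in range(k)
    }
    for feature, k in FEATURE_CATEGORIES.items()
}


def simulate_raters(
    truths: "dict[str, FeatureScores] | FeatureScores",
    error_rates: "dict[str, float] | float" = 0.1,
    n_raters: int = 3,
    seed: int = 0,
) -> RaterPanel:
    """Noisy multi-observer panel around ground-truth scores.

    Each rater reports the truth with probability 1 − ε and otherwise a
    uniformly drawn adjacent category (a flip, for binary features).
    ``error_rates`` may be a scalar or a per-feature mapping.
    """
    if isinstance(truths, FeatureScores):
        truths = {"slide_0": truths}
    if not isinstance(error_rates, dict):
        error_rates = {f: float(error_rates) for f in FEATURE_NAMES}
    for f, eps in error_rates.items():
        if not 0.0 <= eps <= 1.0:
            raise ParameterError(f"error rate for {f} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    import pandas as pd

    rows = []
    for slide_id in sorted(truths):
        fs = truths[slide_id]
        if fs.excluded:
            continue
        for rater in range(n_raters):
            rater_id = f"rater_{rater}"
            for feature in FEATURE_NAMES:
                true_v = getattr(fs, feature)
                eps = error_rates.get(feature, 0.0)
                if rng.random() < eps:
                    neighbors = _ADJACENT[feature][true_v]
                    v = int(neighbors[rng.integers(0, len(neighbors))])
                else:
                    v = int(true_v)
                rows.append((slide_id, rater_id, feature, v))
    return RaterPanel(
        pd.DataFrame(rows, columns=["slide_id", "rater_id", "feature", "score"])
    )


def _draw_categorical(
    rng: np.random.Generator, probs: dict, n: int
) -> np.ndarray:
    keys = list(probs)
    return rng.choice(keys, size=n, p=[probs[k] for k in keys])


def simulate_cohort(
    spec: CohortSpec,
    scores: "list[FeatureScores] | None" = None,
    infiltration: "list[float] | None" = None,
) -> "list[PatientRecord]":
    """Synthetic PFI cohort with planted proportional hazards.

    Event times are exponential (or Weibull, proportional-hazards
    parameterized) with rate baseline × exp(linear predictor); censoring
    is uniform on (0, censoring window]; observed times are rounded up to
    whole days.  When ``scores`` are supplied the high-risk indicator is
    derived through the >= 2-feature rule; otherwise membership is drawn
    Bernoulli(``high_risk_prob``).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    if scores is not None and len(scores) != n:
        raise ParameterError("need one FeatureScores per patient")
    if infiltration is not None and len(infiltration) != n:
        raise ParameterError("need one infiltration value per patient")

    pam50 = _draw_categorical(rng, spec.pam50_probs, n)
    er = _draw_categorical(rng, spec.er_probs, n)
    stage = _draw_categorical(rng, spec.stage_probs, n)

    lp = np.zeros(n)
    high_risk = None
    if "high_risk" in spec.coefficients:
        if scores is not None:
            high_risk = np.array(
                [
                    1.0
                    if high_risk_profile(s).group == "high-risk"
                    else 0.0
                    for s in scores
                ]
            )
        else:
            high_risk = (rng.random(n) < spec.high_risk_prob).astype(float)
        lp += spec.coefficients["high_risk"] * high_risk
    if "infiltration_per_sd" in spec.coefficients:
        if infiltration is None:
            raise ParameterError(
                "infiltration_per_sd coefficient needs infiltration values"
            )
        arr = np.asarray(infiltration, dtype=float)
        sd = arr.std(ddof=1)
        scaled = arr / sd if sd > 0 else arr
        lp += spec.coefficients["infiltration_per_sd"] * scaled

    rate = spec.baseline_rate * np.exp(lp)
    raw = rng.exponential(1.0, size=n)
    if spec.time_distribution == "exponential":
        t_event = raw / rate
    else:
        t_event = (raw / rate) ** (1.0 / spec.weibull_shape)
    t_cens = rng.uniform(0.0, spec.censoring_days, size=n)
    observed = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    days = np.maximum(np.ceil(observed), 1.0)
    if event.sum() == 0:
        import warnings

        warnings.warn("simulated cohort contains zero events", stacklevel=2)

    records = []
    for i in range(n):
        rec = PatientRecord(
            patient_id=f"pt_{i:04d}",
            pfi_days=float(days[i]),
            event=int(event[i]),
            pam50=str(pam50[i]),
            er_status=str(er[i]),
            stage=str(stage[i]),
            percent_infiltration=(
                float(infiltration[i]) if infiltration is not None else None
            ),
            scores=scores[i] if scores is not None else None,
        )
        if high_risk is not None:
            rec.risk_group = "high-risk" if high_risk[i] else "low-risk"
        records.append(rec)
    return records
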