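"""Multi-observer consensus scoring and interrater-agreement screening.

Each slide's spatial features are scored by several independent observers;
consensus is the per-feature median (lower middle value for even panels, so
consensus stays in the ordinal domain).  Features whose Fleiss' kappa falls
below a cutoff (0.5 by default) are screened out of the active high-risk
indicator set — this is how tertiary lymphoid aggregates (kappa 0.37 in the
motivating study) drop out of risk scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .features import FEATURE_CATEGORIES, FEATURE_NAMES, FeatureScores

__all__ = [
    "RaterPanel",
    "KappaReport",
    "consensus_median",
    "fleiss_kappa",
    "ratings_matrix",
    "kappa_report",
    "screen_features",
    "FEATURE_TO_INDICATOR",
]

#: Which high-risk indicator each spatial feature feeds.
FEATURE_TO_INDICATOR = {
    "intratumoral_strength": "low_intratumoral",
    "deserts": "deserts_present",
    "forests": "forests_absent",
    "peritumoral_strength": "low_peritumoral",
    "aggregates": "aggregates_absent",
}


@dataclass
class RaterPanel:
    """Long-format table of per-rater feature scores.

    ``table`` columns: slide_id, rater_id, feature, score.  Each
    (slide_id, rater_id, feature) triple appears at most once; slides a
    rater left unscored are simply absent (no imputation).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"slide_id", "rater_id", "feature", "score"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"panel table missing columns {sorted(missing)}")
        dup = self.table.duplicated(["slide_id", "rater_id", "feature"])
        if dup.any():
            raise ValidationError("duplicate (slide, rater, feature) entries")
        bad = set(self.table["feature"]) - set(FEATURE_NAMES)
        if bad:
            raise ValidationError(f"unknown features in panel: {sorted(bad)}")

    @classmethod
    def from_scores(
        cls, scores: "dict[str, dict[str, FeatureScores]]"
    ) -> "RaterPanel":
        """Build a panel from {slide_id: {rater_id: FeatureScores}}."""
        rows = []
        for slide_id, raters in scores.items():
            for rater_id, fs in raters.items():
                if fs.excluded:
                    continue
                for feature in FEATURE_NAMES:
                    rows.append(
                        (slide_id, rater_id, feature, getattr(fs, feature))
                    )
        return cls(
            pd.DataFrame(rows, columns=["slide_id", "rater_id", "feature", "score"])
        )


@dataclass
class KappaReport:
    """Per-feature Fleiss' kappa with the inclusion decision."""

    feature: str
    kappa: float
    n_slides: int
    n_raters: int
    included: bool = True
    degenerate: bool = False  # every rating in one category


def consensus_median(panel: RaterPanel) -> "dict[str, FeatureScores]":
    """Per-slide consensus: the median rater score for each feature.

    With an even number of raters the lower middle value is taken so the
    consensus remains an ordinal score.  Slides with fewer than two raters
    are excluded with a reason rather than passed through.
    """
    out: dict[str, FeatureScores] = {}
    for slide_id, group in panel.table.groupby("slide_id", sort=True):
        n_raters = group["rater_id"].nunique()
        if n_raters < 2:
            out[slide_id] = FeatureScores(
                excluded=True,
                reason=f"only {n_raters} rater(s); consensus needs >= 2",
            )
            continue
        values: dict[str, int] = {}
        for feature, sub in group.groupby("feature"):
            ranked = np.sort(sub["score"].to_numpy())
            values[feature] = int(ranked[(len(ranked) - 1) // 2])
        out[slide_id] = FeatureScores(**values)
    return out


def fleiss_kappa(counts: np.ndarray) -> tuple[float, bool]:
    """Fleiss' kappa for a slide x category count matrix.

    Each row holds, for one slide, the number of raters assigning each
    category; all rows must sum to the same rater count n >= 2.  Returns
    ``(kappa, degenerate)`` where kappa = (P̄ − P̄e) / (1 − P̄e), P̄ the
    mean per-slide agreement and P̄e the expected agreement from the
    marginal category frequencies.  When every rating falls in a single
    category, chance agreement P̄e is 1 and the ratio is undefined;
    agreement is nonetheless perfect, so kappa is reported as 1.0 with the
    degenerate flag set.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 1:
        raise ValidationError("need a 2-D slide x category count matrix")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValidationError("counts must be non-negative integers")
    row_sums = counts.sum(axis=1)
    n = row_sums[0]
    if n < 2 or not np.all(row_sums == n):
        raise ValidationError(
            "every slide must be rated by the same number (>= 2) of raters"
        )
    N = counts.shape[0]
    p_j = counts.sum(axis=0) / (N * n)
    P_i = (np.square(counts).sum(axis=1) - n) / (n * (n - 1))
    P_bar = P_i.mean()
    P_e = float(np.square(p_j).sum())
    if np.isclose(P_e, 1.0):
        return 1.0, True
    return float((P_bar - P_e) / (1.0 - P_e)), False


def ratings_matrix(panel: RaterPanel, feature: str) -> np.ndarray:
    """Slide x category count matrix for one feature.

    Only slides rated by the modal (largest common) rater count are kept,
    so rows satisfy the equal-rater precondition; slides unscored by some
    raters are dropped, not imputed.
    """
    if feature not in FEATURE_NAMES:
        raise ParameterError(f"unknown feature {feature!r}")
    sub = panel.table[panel.table["feature"] == feature]
    per_slide = sub.groupby("slide_id")["rater_id"].nunique()
    if per_slide.empty:
        raise ValidationError(f"no ratings for feature {feature!r}")
    n = per_slide.max()
    keep = per_slide[per_slide == n].index
    sub = sub[sub["slide_id"].isin(keep)]
    k = FEATURE_CATEGORIES[feature]
    mat = (
        sub.groupby("slide_id")["score"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=range(k), fill_value=0)
    )
    return mat.to_numpy(dtype=float)


def kappa_report(
    panel: RaterPanel, cutoff: float = 0.5
) -> "list[KappaReport]":
    """Fleiss' kappa per feature, with inclusion at the >= cutoff rule."""
    reports = []
    for feature in FEATURE_NAMES:
        mat = ratings_matrix(panel, feature)
        kappa, degenerate = fleiss_kappa(mat)
        reports.append(
            KappaReport(
                feature=feature,
                kappa=kappa,
                n_slides=mat.shape[0],
                n_raters=int(mat[0].sum()),
                included=kappa >= cutoff,
                degenerate=degenerate,
            )
        )
    return reports


def screen_features(
    reports: "list[KappaReport]", cutoff: float = 0.5
) -> frozenset[str]:
    """Active high-risk indicator set after agreement screening.

    Features with kappa below the cutoff are removed; kappa exactly at the
    cutoff is retained (>= rule).
    """
    active = set()
    for rep in reports:
        rep.included = rep.kappa >= cutoff
        if rep.included:
            active.add(FEATURE_TO_INDICATOR[rep.feature])
    return frozenset(active)
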