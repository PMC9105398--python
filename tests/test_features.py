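"""Spatial-feature scoring: components, deserts, forests, strengths, band,
aggregates, and the high-risk indicator mapping."""

from collections import deque

import numpy as np
import pytest

from tilscape import (
    CompositeMap,
    FeatureScores,
    MorphologyConfig,
    ParameterError,
    UndefinedFeatureError,
    connected_components,
    high_risk_profile,
    peritumoral_band,
    score_aggregates,
    score_all,
    score_deserts,
    score_forests,
    score_intratumoral_strength,
    score_peritumoral_strength,
)

CFG = MorphologyConfig()


def _flood_fill_components(grid, connectivity):
    """BFS flood-fill oracle returning component cell-count multiset."""
    grid = np.asarray(grid, dtype=bool)
    seen = np.zeros_like(grid)
    if connectivity == 4:
        nbrs = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                if (dy, dx) != (0, 0)]
    sizes = []
    for sy, sx in np.argwhere(grid):
        if seen[sy, sx]:
            continue
        q, size = deque([(sy, sx)]), 0
        seen[sy, sx] = True
        while q:
            y, x = q.popleft()
            size += 1
            for dy, dx in nbrs:
                ny, nx = y + dy, x + dx
                if (0 <= ny < grid.shape[0] and 0 <= nx < grid.shape[1]
                        and grid[ny, nx] and not seen[ny, nx]):
                    seen[ny, nx] = True
                    q.append((ny, nx))
        sizes.append(size)
    return sorted(sizes)


def _all_tumor_map(lymph):
    lymph = np.asarray(lymph, dtype=bool)
    return CompositeMap(np.ones_like(lymph), lymph, 12.5)


class TestConnectedComponents:
    def test_diagonal_touch_depends_on_connectivity(self):
        grid = np.array([[True, False], [False, True]])
        _, sizes4 = connected_components(grid, 4)
        _, sizes8 = connected_components(grid, 8)
        assert len(sizes4) == 2
        assert len(sizes8) == 1

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(17)
        for _ in range(25):
            grid = rng.random((30, 30)) < 0.45
            _, sizes = connected_components(grid, connectivity)
            assert sorted(sizes.tolist()) == _flood_fill_components(
                grid, connectivity
            )


class TestDeserts:
    def test_quarter_area_block_fires(self):
        lymph = np.ones((20, 20), bool)
        lymph[:10, :10] = False  # 100 of 400 cells TIL-free
        assert score_deserts(_all_tumor_map(lymph), CFG) == 1

    def test_fully_infiltrated_is_zero(self):
        assert score_deserts(_all_tumor_map(np.ones((20, 20), bool)), CFG) == 0

    def test_scattered_singletons_below_min_component_do_not_count(self):
        # 30 isolated TIL-free cells in a 400-cell tumor: each singleton is
        # below the 1% (4-cell) minimum component, so nothing qualifies
        lymph = np.ones((20, 20), bool)
        free = [(2 * i % 20, (7 * i + 3) % 20) for i in range(30)]
        free = {
            (y, x) for y, x in free
        }
        # thin to cells with no 4-neighbors in the set
        free = {
            (y, x)
            for y, x in free
            if not any(
                (y + dy, x + dx) in free
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1))
            )
        }
        for y, x in free:
            lymph[y, x] = False
        cmap = _all_tumor_map(lymph)
        _, sizes = connected_components(cmap.tumor & ~cmap.lymph, 4)
        assert sizes.max() < 0.01 * 400
        assert score_deserts(cmap, CFG) == 0

    def test_empty_tumor_is_undefined(self):
        cmap = CompositeMap(
            np.zeros((5, 5), bool), np.zeros((5, 5), bool), 12.5
        )
        with pytest.raises(UndefinedFeatureError):
            score_deserts(cmap, CFG)

    def test_flip_point_at_quarter_of_tumor_area(self):
        # single contiguous block swept upward: score flips 0->1 exactly
        # at 25% of tumor area
        flips = []
        for k in range(0, 401):
            lymph = np.ones((20, 20), bool)
            flat = np.zeros(400, dtype=bool)
            flat[:k] = True
            lymph[flat.reshape(20, 20)] = False
            s = score_deserts(_all_tumor_map(lymph), CFG)
            flips.append(s)
        first_one = flips.index(1)
        assert first_one == 100  # 100/400 = 25%
        assert all(v == 0 for v in flips[:100])


class TestForests:
    def test_ten_percent_block_fires(self):
        lymph = np.zeros((20, 20), bool)
        lymph[:4, :10] = True  # one 40-cell confluent block = 10%
        assert score_forests(_all_tumor_map(lymph), CFG) == 1

    def test_no_intratumoral_tils_is_zero(self):
        assert score_forests(_all_tumor_map(np.zeros((20, 20), bool)), CFG) == 0

    def test_two_small_groups_do_not_fire(self):
        # two 4-cell clusters (2% total) stay below both the qualifying
        # minimum and the 10% area rule
        lymph = np.zeros((20, 20), bool)
        lymph[0:2, 0:2] = True
        lymph[10:12, 10:12] = True
        assert score_forests(_all_tumor_map(lymph), CFG) == 0

    def test_flip_point_at_ten_percent(self):
        flips = []
        for k in range(0, 101):
            lymph = np.zeros((20, 20), bool)
            flat = np.zeros(400, dtype=bool)
            flat[:k] = True
            lymph[flat.reshape(20, 20)] = True
            flips.append(score_forests(_all_tumor_map(lymph), CFG))
        assert flips.index(1) == 40  # 40/400 = 10%


def _desert_forest_oracle(cmap, cfg):
    """Flood-fill + area-sum oracle for the two binary confluence calls."""
    area = int(cmap.tumor.sum())
    out = []
    for mask, min_frac, thr in (
        (cmap.tumor & ~cmap.lymph, cfg.desert_min_component_frac,
         cfg.desert_area_frac_threshold),
        (cmap.tumor & cmap.lymph, cfg.forest_min_component_frac,
         cfg.forest_area_frac_threshold),
    ):
        sizes = _flood_fill_components(mask, cfg.connectivity)
        total = sum(s for s in sizes if s >= min_frac * area)
        out.append(int(total >= thr * area))
    return tuple(out)


class TestDesertForestOracle:
    def test_agreement_on_random_maps(self):
        rng = np.random.default_rng(23)
        for _ in range(60):
            tumor = rng.random((40, 40)) < rng.uniform(0.4, 0.95)
            lymph = rng.random((40, 40)) < rng.uniform(0.05, 0.6)
            if not tumor.any():
                continue
            cmap = CompositeMap(tumor, lymph, 12.5)
            d, f = _desert_forest_oracle(cmap, CFG)
            assert score_deserts(cmap, CFG) == d
            assert score_forests(cmap, CFG) == f


class TestIntratumoralStrength:
    def test_zero_without_any_intratumoral_tils(self):
        assert score_intratumoral_strength(
            _all_tumor_map(np.zeros((20, 20), bool)), CFG
        ) == 0

    def test_twenty_percent_is_strong(self):
        lymph = np.zeros((20, 20), bool)
        flat = np.zeros(400, dtype=bool)
        flat[:80] = True  # 20% infiltration
        lymph[flat.reshape(20, 20)] = True
        assert score_intratumoral_strength(_all_tumor_map(lymph), CFG) == 3

    def test_monotone_in_infiltration(self):
        prev = -1
        for k in range(0, 401, 10):
            lymph = np.zeros((20, 20), bool)
            flat = np.zeros(400, dtype=bool)
            flat[:k] = True
            lymph[flat.reshape(20, 20)] = True
            s = score_intratumoral_strength(_all_tumor_map(lymph), CFG)
            assert s >= prev
            prev = s
        assert prev == 3


def _band_oracle(tumor, width, connectivity):
    """Per-cell distance oracle for the peritumoral band."""
    tumor = np.asarray(tumor, dtype=bool)
    band = np.zeros_like(tumor)
    tcells = np.argwhere(tumor)
    for y in range(tumor.shape[0]):
        for x in range(tumor.shape[1]):
            if tumor[y, x]:
                continue
            dy = np.abs(tcells[:, 0] - y)
            dx = np.abs(tcells[:, 1] - x)
            d = (
                np.maximum(dy, dx) if connectivity == 8 else dy + dx
            ).min()
            band[y, x] = d <= width
    return band


class TestPeritumoralBand:
    def test_single_cell_eight_ring(self):
        tumor = np.zeros((5, 5), bool)
        tumor[2, 2] = True
        band = peritumoral_band(CompositeMap(tumor, np.zeros_like(tumor), 12.5),
                                MorphologyConfig(band_width_cells=1))
        assert band.sum() == 8
        assert not band[2, 2]

    def test_tumor_filling_grid_has_empty_band(self):
        cmap = _all_tumor_map(np.zeros((6, 6), bool))
        assert peritumoral_band(cmap, CFG).sum() == 0

    @pytest.mark.parametrize("dilation_connectivity", [4, 8])
    def test_matches_distance_oracle_on_random_blob(self, dilation_connectivity):
        rng = np.random.default_rng(31)
        tumor = np.zeros((25, 25), bool)
        yy, xx = np.mgrid[0:25, 0:25]
        for _ in range(3):
            cy, cx, r = rng.integers(5, 20, 3)
            tumor |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2 // 4
        cfg = MorphologyConfig(
            band_width_cells=3, dilation_connectivity=dilation_connectivity
        )
        cmap = CompositeMap(tumor, np.zeros_like(tumor), 12.5)
        np.testing.assert_array_equal(
            peritumoral_band(cmap, cfg),
            _band_oracle(tumor, 3, dilation_connectivity),
        )


class TestPeritumoralStrength:
    def _map_with_band_fraction(self, frac):
        tumor = np.zeros((30, 30), bool)
        tumor[10:20, 10:20] = True
        cmap = CompositeMap(tumor, np.zeros_like(tumor), 12.5)
        band = peritumoral_band(cmap, CFG)
        cells = np.argwhere(band)
        k = int(round(frac * len(cells)))
        lymph = np.zeros_like(tumor)
        lymph[tuple(cells[:k].T)] = True
        return CompositeMap(tumor, lymph, 12.5)

    def test_silent_band_is_zero(self):
        assert score_peritumoral_strength(self._map_with_band_fraction(0.0),
                                          CFG) == 0

    def test_saturated_band_is_three(self):
        assert score_peritumoral_strength(self._map_with_band_fraction(1.0),
                                          CFG) == 3

    def test_ten_percent_band_is_two(self):
        assert score_peritumoral_strength(self._map_with_band_fraction(0.10),
                                          CFG) == 2

    def test_empty_band_is_undefined(self):
        with pytest.raises(UndefinedFeatureError):
            score_peritumoral_strength(
                _all_tumor_map(np.zeros((6, 6), bool)), CFG
            )


class TestAggregates:
    def _base(self):
        tumor = np.zeros((40, 40), bool)
        tumor[15:25, 15:25] = True
        return tumor

    def test_no_distal_lymph_is_zero(self):
        tumor = self._base()
        assert score_aggregates(
            CompositeMap(tumor, np.zeros_like(tumor), 12.5), CFG
        ) == 0

    def test_two_distal_clusters_fire(self):
        tumor = self._base()
        lymph = np.zeros_like(tumor)
        lymph[2:4, 2:5] = True  # 6 cells, far corner
        lymph[35:37, 33:36] = True  # 6 cells, opposite corner
        assert score_aggregates(CompositeMap(tumor, lymph, 12.5), CFG) == 1

    def test_single_large_cluster_is_not_multifocal(self):
        tumor = self._base()
        lymph = np.zeros_like(tumor)
        lymph[2:6, 2:10] = True
        assert score_aggregates(CompositeMap(tumor, lymph, 12.5), CFG) == 0

    def test_band_touching_cluster_does_not_count(self):
        tumor = self._base()
        lymph = np.zeros_like(tumor)
        lymph[25:28, 15:20] = True  # starts right at the tumor edge
        lymph[2:4, 2:5] = True
        assert score_aggregates(CompositeMap(tumor, lymph, 12.5), CFG) == 0


class TestScoreAll:
    def test_cold_all_tumor_map(self):
        # all-tumor, no lymph anywhere: desert forced (100% >= 25%), all
        # strengths 0 — but peritumoral is undefined (no band), so build a
        # blob that leaves a boundary
        tumor = np.zeros((30, 30), bool)
        tumor[5:25, 5:25] = True
        scores = score_all(CompositeMap(tumor, np.zeros_like(tumor), 12.5))
        assert (
            scores.intratumoral_strength,
            scores.deserts,
            scores.forests,
            scores.peritumoral_strength,
            scores.aggregates,
        ) == (0, 1, 0, 0, 0)

    def test_hot_map_with_everything(self):
        rng = np.random.default_rng(2)
        tumor = np.zeros((40, 40), bool)
        tumor[12:28, 12:28] = True
        lymph = np.zeros_like(tumor)
        # dense diffuse: TIL-free area 20% < 25%, so no desert can qualify
        lymph[tumor] = rng.random(int(tumor.sum())) < 0.8
        cmap0 = CompositeMap(tumor, lymph, 12.5)
        band = peritumoral_band(cmap0, CFG)
        lymph[band] = True  # saturated band
        lymph[2:5, 2:6] = True  # two distal clusters
        lymph[35:38, 30:34] = True
        scores = score_all(CompositeMap(tumor, lymph, 12.5))
        assert scores.intratumoral_strength == 3
        assert scores.deserts == 0
        assert scores.forests == 1
        assert scores.peritumoral_strength == 3
        assert scores.aggregates == 1

    def test_tumorless_map_is_excluded(self):
        scores = score_all(
            CompositeMap(np.zeros((5, 5), bool), np.zeros((5, 5), bool), 12.5)
        )
        assert scores.excluded
        assert scores.reason


class TestHighRiskProfile:
    def test_favorable_profile_is_low_risk(self):
        p = high_risk_profile(
            FeatureScores(3, 0, 1, 3, 1)
        )
        assert (p.count, p.group) == (0, "low-risk")

    def test_every_default_indicator_fires(self):
        p = high_risk_profile(FeatureScores(1, 1, 0, 1, 1))
        assert p.count == 4
        assert p.group == "high-risk"

    def test_single_indicator_is_low_risk(self):
        p = high_risk_profile(FeatureScores(0, 0, 1, 2, 1))
        assert p.indicators == frozenset({"low_intratumoral"})
        assert p.group == "low-risk"

    def test_aggregates_only_counted_when_active(self):
        scores = FeatureScores(3, 0, 1, 3, 0)
        assert high_risk_profile(scores).count == 0
        p = high_risk_profile(
            scores,
            active=frozenset(
                {"low_intratumoral", "deserts_present", "forests_absent",
                 "low_peritumoral", "aggregates_absent"}
            ),
        )
        assert p.count == 1

    def test_excluded_scores_are_refused(self):
        with pytest.raises(UndefinedFeatureError):
            high_risk_profile(FeatureScores(excluded=True, reason="qc"))

    def test_monotone_in_firing_indicators(self):
        # turning one more indicator on never demotes high-risk to low-risk
        base = FeatureScores(2, 0, 1, 2, 1)  # nothing fires
        worse_steps = [
            FeatureScores(1, 0, 1, 2, 1),
            FeatureScores(1, 1, 1, 2, 1),
            FeatureScores(1, 1, 0, 2, 1),
            FeatureScores(1, 1, 0, 1, 1),
        ]
        counts = [high_risk_profile(s).count for s in [base] + worse_steps]
        assert counts == sorted(counts)
        groups = [high_risk_profile(s).group for s in [base] + worse_steps]
        assert "low-risk" not in groups[groups.index("high-risk"):]
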