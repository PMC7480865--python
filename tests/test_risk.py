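"""Binary maps, population at risk, overlap, IU classification, shares."""

import numpy as np
import pytest

from podomap.grid import GridRaster, GridSpec
from podomap.risk import (
    RiskError,
    binarize,
    classify_ius,
    overlap_binary,
    population_at_risk,
    rasterize_zones,
    share_percentage,
    share_percentages,
)


@pytest.fixture
def spec2():
    return GridSpec(2, 2, 0.0, 0.0, 1.0)


class TestBinarize:
    def test_extremes(self, spec2):
        suit = GridRaster(spec2, np.array([[0.1, 0.5], [0.9, 0.3]]))
        assert (binarize(suit, 0.0).raster.values == 1).all()
        assert (binarize(suit, 1.0).raster.values == 0).all()

    def test_threshold_inclusive(self, spec2):
        suit = GridRaster(GridSpec(1, 3, 0, 0, 1.0),
                          np.array([[0.38, 0.389, 0.40]]))
        out = binarize(suit, 0.389)
        np.testing.assert_array_equal(out.raster.values, [[0.0, 1.0, 1.0]])

    def test_mask_preserved(self, spec2):
        mask = np.array([[True, False], [False, False]])
        suit = GridRaster(spec2, np.full((2, 2), 0.6), mask)
        out = binarize(suit, 0.5)
        assert out.raster.nodata_mask[0, 0]

    def test_invalid_threshold(self, spec2):
        suit = GridRaster(spec2, np.zeros((2, 2)))
        with pytest.raises(RiskError):
            binarize(suit, 1.5)


class TestPopulationAtRisk:
    def test_hand_sum_single_zone(self, spec2):
        pop = GridRaster(spec2, np.array([[10.0, 20.0], [30.0, 40.0]]))
        suit = GridRaster(spec2, np.array([[1.0, 0.0], [1.0, 0.0]]))
        zones = GridRaster(spec2, np.zeros((2, 2)))
        summary = population_at_risk(binarize(suit, 0.5), pop, [], zones)
        assert summary.total[0] == 40.0

    def test_all_suitable_conserves_total(self, spec2):
        pop = GridRaster(spec2, np.array([[1.0, 2.0], [4.0, 8.0]]))
        suit = GridRaster(spec2, np.ones((2, 2)))
        zones = GridRaster(spec2, np.array([[0.0, 0.0], [1.0, 1.0]]))
        summary = population_at_risk(binarize(suit, 0.5), pop, [], zones)
        assert summary.total[0] == 15.0
        assert sum(v[0] for v in summary.per_zone.values()) == summary.total[0]

    def test_degenerate_interval(self, spec2):
        pop = GridRaster(spec2, np.full((2, 2), 5.0))
        suit = GridRaster(spec2, np.array([[1.0, 0.0], [0.0, 0.0]]))
        zones = GridRaster(spec2, np.zeros((2, 2)))
        bm = binarize(suit, 0.5)
        summary = population_at_risk(bm, pop, [bm, bm, bm], zones)
        assert summary.total == (5.0, 5.0, 5.0)

    def test_zone_conservation_random_partition(self):
        rng = np.random.default_rng(0)
        spec = GridSpec(10, 10, 0.0, 0.0, 1.0)
        pop = GridRaster(spec, rng.integers(0, 100, (10, 10)).astype(float))
        suit = GridRaster(spec, rng.random((10, 10)))
        zones = GridRaster(spec, rng.integers(0, 5, (10, 10)).astype(float))
        summary = population_at_risk(binarize(suit, 0.4), pop, [], zones)
        assert sum(v[0] for v in summary.per_zone.values()) == summary.total[0]

    def test_misaligned_errors(self, spec2):
        pop = GridRaster(GridSpec(2, 2, 1.0, 0.0, 1.0), np.ones((2, 2)))
        suit = GridRaster(spec2, np.ones((2, 2)))
        zones = GridRaster(spec2, np.zeros((2, 2)))
        with pytest.raises(RiskError):
            population_at_risk(binarize(suit, 0.5), pop, [], zones)


class TestOverlap:
    def test_enumerated_classes(self, spec2):
        a = binarize(GridRaster(spec2, np.array([[1.0, 1.0], [0.0, 0.0]])), 0.5)
        b = binarize(GridRaster(spec2, np.array([[1.0, 0.0], [1.0, 0.0]])), 0.5)
        pop = GridRaster(spec2, np.array([[1.0, 2.0], [4.0, 8.0]]))
        _, pops = overlap_binary(a, b, pop)
        assert pops == {"both": 1.0, "a_only": 2.0, "b_only": 4.0, "neither": 8.0}

    def test_identical_maps(self, spec2):
        a = binarize(GridRaster(spec2, np.array([[1.0, 0.0], [1.0, 0.0]])), 0.5)
        pop = GridRaster(spec2, np.ones((2, 2)))
        _, pops = overlap_binary(a, a, pop)
        assert pops["a_only"] == 0.0 and pops["b_only"] == 0.0

    def test_partition_of_total(self, spec2):
        rng = np.random.default_rng(1)
        a = binarize(GridRaster(spec2, rng.random((2, 2))), 0.5)
        b = binarize(GridRaster(spec2, rng.random((2, 2))), 0.5)
        pop = GridRaster(spec2, rng.integers(1, 50, (2, 2)).astype(float))
        _, pops = overlap_binary(a, b, pop)
        assert sum(pops.values()) == pop.values.sum()


class TestClassifyIUs:
    @pytest.fixture
    def scene(self):
        spec = GridSpec(2, 4, 0.0, 0.0, 1.0)
        suit = GridRaster(spec, np.array([[1.0, 1.0, 0.0, 0.0],
                                          [1.0, 0.0, 0.0, 1.0]]))
        ius = GridRaster(spec, np.array([[0.0, 0.0, 1.0, 1.0],
                                         [2.0, 2.0, 3.0, 3.0]]))
        return binarize(suit, 0.5), ius

    def test_any_cell_rule(self, scene):
        binary, ius = scene
        out = classify_ius(binary, ius, {})
        by_id = out.table.set_index("iu_id")
        assert bool(by_id.loc[0, "suitable"])
        assert not bool(by_id.loc[1, "suitable"])
        assert bool(by_id.loc[3, "suitable"])

    def test_needs_mapping_counts(self, scene):
        binary, ius = scene
        out = classify_ius(binary, ius, {0: True})  # IU 0 mapped, 2 and 3 not
        assert out.n_suitable == 3
        assert out.n_needs_mapping == 2

    def test_min_fraction_rule(self, scene):
        binary, ius = scene
        out = classify_ius(binary, ius, {}, min_fraction=0.6)
        by_id = out.table.set_index("iu_id")
        assert bool(by_id.loc[0, "suitable"])  # 2/2 suitable cells
        assert not bool(by_id.loc[3, "suitable"])  # 1/2 = 0.5 <= 0.6

    def test_matches_brute_force_any_cell(self):
        rng = np.random.default_rng(5)
        spec = GridSpec(6, 6, 0.0, 0.0, 1.0)
        suit = GridRaster(spec, (rng.random((6, 6)) > 0.6).astype(float))
        ius = GridRaster(spec, rng.integers(0, 4, (6, 6)).astype(float))
        out = classify_ius(binarize(suit, 0.5), ius, {})
        for _, row in out.table.iterrows():
            cells = ius.values == row["iu_id"]
            assert row["suitable"] == bool((suit.values[cells] == 1).any())

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        spec = GridSpec(8, 8, 0.0, 0.0, 1.0)
        suit = GridRaster(spec, rng.random((8, 8)))
        pop = GridRaster(spec, rng.integers(1, 100, (8, 8)).astype(float))
        ius = GridRaster(spec, rng.integers(0, 6, (8, 8)).astype(float))
        zones = GridRaster(spec, np.zeros((8, 8)))
        last_pop, last_ius = -np.inf, -np.inf
        for t in [0.9, 0.7, 0.5, 0.3, 0.1]:
            bm = binarize(suit, t)
            s = population_at_risk(bm, pop, [], zones)
            n = classify_ius(bm, ius, {}).n_suitable
            assert s.total[0] >= last_pop and n >= last_ius
            last_pop, last_ius = s.total[0], n


class TestShares:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(1311, 2870, 45.7), (1655, 5712, 29.0), (960, 1655, 58.0),
         (495, 1655, 29.9), (1, 3, 33.3), (1, 8, 12.5)],
    )
    def test_values(self, num, den, expected):
        assert share_percentage(num, den) == expected

    def test_half_up_rounding(self):
        assert share_percentage(125, 1000) == 12.5
        assert share_percentage(1250, 100000) == 1.3  # 1.25 rounds up, not to even

    def test_vector_form_and_zero_denominator(self):
        assert share_percentages([1, 2], 4) == [25.0, 50.0]
        with pytest.raises(RiskError):
            share_percentage(1, 0)


class TestRasterizeZones:
    def test_cell_centre_rule(self):
        spec = GridSpec(2, 2, 0.0, 0.0, 1.0)
        gj = {
            "type": "FeatureCollection",
            "features": [{
                "type": "Feature",
                "properties": {"zone_id": 7},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[0, 0], [1, 0], [1, 2], [0, 2], [0, 0]]],
                },
            }],
        }
        out = rasterize_zones(gj, spec)
        np.testing.assert_array_equal(out.values[:, 0], [7.0, 7.0])
        assert out.nodata_mask[:, 1].all()
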