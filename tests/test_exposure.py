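"""Exposure metrics: window frequencies, ensemble statistics, multi-hazard
counting and area/overlap-weighted entity exposure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hazex import AreaWeights, Grid, RangeMask
from hazex import exposure as ex
from hazex import synthetic as syn
from hazex.events import EventMatrix
from hazex.exposure import ExposureError, FrequencyField


def event_matrix_one_cell(flag_years, years=range(1985, 2015), event="heatwave"):
    yrs = np.array(list(years))
    flags = np.zeros((len(yrs), 1, 1), dtype=bool)
    for y in flag_years:
        flags[list(yrs).index(y), 0, 0] = True
    return EventMatrix(
        years=yrs, flags={event: flags}, valid={event: np.ones((1, 1), bool)}
    )


class TestWindowFrequency:
    def test_15_of_30_years_gives_half(self):
        m = event_matrix_one_cell(range(1985, 2000))
        f = ex.window_frequency(m, 2000, "heatwave")
        assert f.frequency[0, 0] == pytest.approx(0.5)

    def test_zero_and_full_windows(self):
        assert ex.window_frequency(event_matrix_one_cell([]), 2000, "heatwave").frequency[0, 0] == 0.0
        m = event_matrix_one_cell(range(1985, 2015))
        assert ex.window_frequency(m, 2000, "heatwave").frequency[0, 0] == 1.0

    def test_baseline_window_is_1985_2014(self):
        assert ex.window_years(2000, 30) == (1985, 2014)

    def test_window_outside_data_rejected(self):
        m = event_matrix_one_cell([])
        with pytest.raises(ExposureError):
            ex.window_frequency(m, 2030, "heatwave")


class TestFrequencyChange:
    def _field(self, count):
        return FrequencyField("heatwave", 2000, np.array([[count]]), width=30)

    def test_zero_to_half_is_plus_half(self):
        assert ex.frequency_change(self._field(15), self._field(0))[0, 0] == pytest.approx(0.5)

    def test_identical_fields_zero(self):
        assert ex.frequency_change(self._field(7), self._field(7))[0, 0] == 0.0

    def test_full_reversal_is_minus_one(self):
        assert ex.frequency_change(self._field(0), self._field(30))[0, 0] == -1.0

    def test_grid_mismatch_rejected(self):
        other = FrequencyField("heatwave", 2000, np.zeros((2, 2), int), width=30)
        with pytest.raises(ExposureError):
            ex.frequency_change(self._field(1), other)

    def test_event_type_mismatch_rejected(self):
        other = FrequencyField("drought", 2000, np.array([[1]]), width=30)
        with pytest.raises(ExposureError):
            ex.frequency_change(self._field(1), other)


class TestEnsembleStats:
    def test_single_member(self):
        m, lo, hi = ex.ensemble_stats([np.array([0.3])])
        assert m == lo == hi == 0.3

    def test_three_values(self):
        m, lo, hi = ex.ensemble_stats([0.2, 0.4, 0.9])
        assert (m, lo, hi) == (pytest.approx(0.5), 0.2, 0.9)

    def test_permutation_invariant(self):
        a = ex.ensemble_stats([0.1, 0.7, 0.4])
        b = ex.ensemble_stats([0.7, 0.4, 0.1])
        assert a == pytest.approx(b)

    def test_empty_rejected(self):
        with pytest.raises(ExposureError):
            ex.ensemble_stats([])


def freq_fields(counts_by_event, width=30):
    return {
        e: FrequencyField(e, 2050, np.asarray(c), width=width)
        for e, c in counts_by_event.items()
    }


class TestMultiHazard:
    def test_counts_at_default_threshold(self):
        f = freq_fields({"heatwave": [[12]], "drought": [[11]], "flood": [[3]], "wildfire": [[0]]})
        assert ex.multi_hazard_count(f, 0.33)[0, 0] == 2

    def test_same_cell_looser_threshold(self):
        f = freq_fields({"heatwave": [[12]], "drought": [[11]], "flood": [[3]], "wildfire": [[0]]})
        # 0.40, 0.3667, 0.10, 0.0 at threshold 0.2 -> 2 qualify... flood 0.1 < 0.2
        assert ex.multi_hazard_count(f, 0.2)[0, 0] == 2
        f2 = freq_fields({"heatwave": [[12]], "drought": [[11]], "flood": [[6]], "wildfire": [[0]]})
        assert ex.multi_hazard_count(f2, 0.2)[0, 0] == 3

    def test_10_of_30_meets_one_third_criterion(self):
        f = freq_fields({"heatwave": [[10]]})
        assert ex.multi_hazard_count(f, 0.33)[0, 0] == 1

    def test_non_increasing_in_threshold(self):
        rng = np.random.default_rng(1)
        f = freq_fields({e: rng.integers(0, 31, (4, 4)) for e in ("heatwave", "drought", "flood", "wildfire")})
        prev = None
        for thr in (0.2, 0.3, 0.33, 0.4, 0.5):
            c = ex.multi_hazard_count(f, thr)
            if prev is not None:
                assert np.all(c <= prev)
            prev = c


class TestEntityExposure:
    def test_single_cell_identity(self):
        f = FrequencyField("heatwave", 2050, np.array([[21]]), width=30)
        mask = RangeMask("sp", np.array([[1.0]]))
        areas = AreaWeights(np.array([[100.0]]))
        assert ex.entity_exposure(f, mask, areas) == pytest.approx(21 / 30)

    def test_two_equal_cells_average(self):
        f = np.array([[0.0, 1.0]])
        mask = RangeMask("sp", np.array([[1.0, 1.0]]))
        areas = AreaWeights(np.array([[5.0, 5.0]]))
        assert ex.entity_exposure(f, mask, areas) == pytest.approx(0.5)

    def test_four_cell_hand_computed_weighted_sum(self):
        freqs = np.array([[0.1, 0.4], [0.9, 0.0]])
        overlap = np.array([[1.0, 0.5], [0.25, 0.8]])
        area = np.array([[2.0, 2.0], [1.0, 1.0]])
        num = 0.1 * 2 * 1.0 + 0.4 * 2 * 0.5 + 0.9 * 1 * 0.25 + 0.0
        den = 2 * 1.0 + 2 * 0.5 + 1 * 0.25 + 1 * 0.8
        expected = num / den
        got = ex.entity_exposure(freqs, RangeMask("sp", overlap), AreaWeights(area))
        assert got == pytest.approx(expected)

    def test_empty_range_rejected(self):
        f = np.zeros((2, 2))
        with pytest.raises(ExposureError):
            ex.entity_exposure(f, RangeMask("sp", np.zeros((2, 2))), AreaWeights(np.ones((2, 2))))

    def test_split_overlap_invariance(self):
        # splitting one cell's overlap across two co-located pseudo-cells
        # (modelled as two columns with equal frequency) leaves exposure fixed
        f_merged = np.array([[0.6, 0.2]])
        m_merged = RangeMask("a", np.array([[0.8, 0.4]]))
        a_merged = AreaWeights(np.array([[3.0, 1.0]]))
        f_split = np.array([[0.6, 0.6, 0.2]])
        m_split = RangeMask("a", np.array([[0.5, 0.3, 0.4]]))
        a_split = AreaWeights(np.array([[3.0, 3.0, 1.0]]))
        assert ex.entity_exposure(f_merged, m_merged, a_merged) == pytest.approx(
            ex.entity_exposure(f_split, m_split, a_split)
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 30), min_size=4, max_size=4),
        overlaps=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
    )
    def test_exposure_bounded_by_cell_frequencies(self, counts, overlaps):
        f = np.array(counts, dtype=float).reshape(2, 2) / 30
        mask = RangeMask("sp", np.array(overlaps).reshape(2, 2))
        areas = AreaWeights(np.array([[2.0, 1.0], [1.5, 0.5]]))
        e = ex.entity_exposure(f, mask, areas)
        assert f.min() - 1e-12 <= e <= f.max() + 1e-12
        if len(set(counts)) == 1:
            assert e == pytest.approx(f.min())


class TestMultiExposure:
    def _inputs(self, counts):
        f = freq_fields({e: c for e, c in zip(("heatwave", "drought", "flood", "wildfire"), counts)})
        mask = RangeMask("sp", np.ones((1, 2)))
        areas = AreaWeights(np.ones((1, 2)))
        return f, mask, areas

    def test_all_cells_qualify(self):
        f, mask, areas = self._inputs([[[30, 30]], [[30, 30]], [[0, 0]], [[0, 0]]])
        assert ex.entity_multi_exposure(f, mask, areas, min_types=2) == 1.0

    def test_no_cell_qualifies(self):
        f, mask, areas = self._inputs([[[30, 30]], [[0, 0]], [[0, 0]], [[0, 0]]])
        assert ex.entity_multi_exposure(f, mask, areas, min_types=2) == 0.0

    def test_order_nesting(self):
        rng = np.random.default_rng(2)
        f = freq_fields({e: rng.integers(0, 31, (3, 3)) for e in ("heatwave", "drought", "flood", "wildfire")})
        mask = RangeMask("sp", rng.uniform(0.1, 1, (3, 3)))
        areas = AreaWeights(np.ones((3, 3)))
        vals = [ex.entity_multi_exposure(f, mask, areas, min_types=k) for k in (1, 2, 3)]
        assert vals[0] >= vals[1] >= vals[2]


class TestCountEntities:
    def _table(self, exposures):
        return pd.DataFrame(
            {
                "entity_id": [f"sp{i}" for i in range(len(exposures))],
                "taxon": ["bird" if i % 2 else "mammal" for i in range(len(exposures))],
                "exposure": exposures,
            }
        )

    def test_cutoff_zero_counts_all(self):
        df = self._table([0.0, 0.2, 0.9, 1.0])
        assert ex.count_entities_above(df, 0.0).sum() == 4

    def test_cutoff_one_excludes_partial(self):
        df = self._table([0.99, 1.0])
        counts = ex.count_entities_above(df, 1.0)
        assert counts.sum() == 1

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(size=50)
        df = self._table(list(vals))
        got = ex.count_entities_above(df, 0.5)
        for taxon in ("bird", "mammal"):
            brute = sum(
                1 for _, r in df.iterrows() if r.taxon == taxon and r.exposure >= 0.5
            )
            assert got[taxon] == brute


class TestRichness:
    def test_single_species_single_cell(self):
        m = RangeMask("sp", np.array([[0.0, 0.7], [0.0, 0.0]]))
        np.testing.assert_array_equal(ex.richness_map([m]), [[0, 1], [0, 0]])

    def test_disjoint_ranges_additive(self):
        a = RangeMask("a", np.array([[1.0, 0.0]]))
        b = RangeMask("b", np.array([[0.0, 0.4]]))
        np.testing.assert_array_equal(ex.richness_map([a, b]), [[1, 1]])

    def test_no_masks_rejected(self):
        with pytest.raises(ExposureError):
            ex.richness_map([])


class TestPartitionConservation:
    def test_ecoregion_exposures_reconstruct_land_mean(self, small_grid, small_areas):
        """Area-weighting ecoregion exposures over the partition recovers the
        global land-mean frequency to near machine precision."""
        rng = np.random.default_rng(4)
        freq = rng.uniform(size=small_grid.shape)
        regions = syn.generate_ecoregions(small_grid, 7, seed=5)
        num = den = 0.0
        for r in regions:
            w = (small_areas.area * r.overlap).sum()
            num += ex.entity_exposure(freq, r, small_areas) * w
            den += w
        land = small_grid.land_mask
        global_mean = (freq[land] * small_areas.area[land]).sum() / small_areas.area[land].sum()
        assert num / den == pytest.approx(global_mean, rel=1e-9)
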