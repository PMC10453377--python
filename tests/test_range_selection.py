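"""Segmentation, combination enumeration and the RMSECV search."""

import logging
import math

import numpy as np
import pytest

from nirbran import (
    cross_validate,
    enumerate_combinations,
    fit_spectral_model,
    format_ranges,
    fuse,
    optimize,
    segment,
)


class TestSegment:
    def test_even_partition(self):
        sch = segment(100, 10)
        assert all(b - a == 10 for a, b in sch.boundaries)

    def test_remainder_goes_to_first_segments(self):
        sch = segment(103, 10)
        sizes = [b - a for a, b in sch.boundaries]
        assert sizes == [11, 11, 11, 10, 10, 10, 10, 10, 10, 10]

    def test_boundaries_partition_axis(self):
        sch = segment(57, 10)
        covered = np.concatenate([np.arange(a, b) for a, b in sch.boundaries])
        np.testing.assert_array_equal(covered, np.arange(57))

    def test_too_few_variables_rejected(self):
        with pytest.raises(ValueError, match="cannot cut"):
            segment(9, 10)


class TestEnumerateCombinations:
    def test_one_to_six_of_ten_count(self):
        combos = enumerate_combinations(10, 1, 6)
        assert len(combos) == sum(math.comb(10, k) for k in range(1, 7)) == 847
        assert len(set(combos)) == 847  # deduplicated

    def test_small_case_listed(self):
        assert enumerate_combinations(3, 1, 2) == [
            (0,), (1,), (2,), (0, 1), (0, 2), (1, 2)
        ]

    def test_all_segments_single_set(self):
        assert enumerate_combinations(10, 10, 10) == [tuple(range(10))]

    def test_seeded_subsample_is_reproducible(self):
        a = enumerate_combinations(10, 1, 6, sample=50, seed=3)
        b = enumerate_combinations(10, 1, 6, sample=50, seed=3)
        assert a == b and len(a) == 50


class TestOptimize:
    def _signal_in_segment(self, seg, n=40, p=50, seed=0):
        """Response driven only by variables of one 10-segment block."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        sch = segment(p, 10)
        cols = np.arange(*sch.boundaries[seg])
        y = X[:, cols].mean(axis=1) + rng.normal(0, 0.01, n) + 4.0
        return X, y

    def test_best_combination_contains_signal_segment(self):
        X, y = self._signal_in_segment(4)
        res = optimize(X, y, conditions=("none",), k_max=2)
        assert 4 in res.best["segments"]

    def test_search_equals_direct_cross_validation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 12))
        y = X[:, 0] + rng.normal(0, 0.1, 30) + 4.0
        res = optimize(X, y, conditions=("none",), n_segments=3, k_min=1, k_max=1)
        sch = segment(12, 3)
        for _, row in res.table.iterrows():
            cols = sch.columns(row["segments"])
            direct = cross_validate(X[:, cols], y, max_lvs=3)
            assert row["rmsecv"] == pytest.approx(direct.best_rmsecv)
            assert row["n_lvs"] == direct.best_lvs

    def test_result_invariant_to_condition_order(self):
        X, y = self._signal_in_segment(2, seed=5)
        a = optimize(X, y, conditions=("none", "SNV"), k_max=2)
        b = optimize(X, y, conditions=("SNV", "none"), k_max=2)
        assert a.best["rmsecv"] == pytest.approx(b.best["rmsecv"])
        assert a.best["segments"] == b.best["segments"]

    def test_best_beats_full_spectrum_when_included(self):
        X, y = self._signal_in_segment(7, seed=9)
        res = optimize(X, y, conditions=("none",), k_min=1, k_max=10)
        full = cross_validate(X, y, max_lvs=4)
        assert res.best["rmsecv"] <= full.best_rmsecv + 1e-12

    def test_table_sorted_ascending(self):
        X, y = self._signal_in_segment(1, seed=3)
        res = optimize(X, y, conditions=("none",), k_max=2)
        assert res.table["rmsecv"].is_monotonic_increasing

    def test_thin_candidates_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(2)
        # cap floor(60/10)=6: combinations below 7 variables are inadmissible
        X = rng.normal(size=(60, 12))
        y = X[:, 0] + 5.0 + rng.normal(0, 0.1, 60)
        with caplog.at_level(logging.WARNING, logger="nirbran"):
            res = optimize(X, y, conditions=("none",), n_segments=6,
                           k_min=1, k_max=4)
        assert "skipping" in caplog.text
        # 1- and 2-segment candidates (2 and 4 variables) are inadmissible
        assert res.table["segments"].map(len).min() == 3


class TestFormatRanges:
    def test_single_block_high_low_notation(self, small_pair):
        dr, _ = small_pair
        cols = np.arange(10, 20)
        text = format_ranges(cols, dr)
        hi = dr.wavenumbers[19]
        lo = dr.wavenumbers[10]
        assert text == f"DR {hi:g}-{lo:g}"

    def test_fused_ranges_tagged_and_split_at_junction(self, small_pair):
        fused = fuse(*small_pair, "raw")
        j = small_pair[0].n_variables
        cols = np.arange(j - 3, j + 3)  # straddles the junction
        text = format_ranges(cols, fused)
        assert "DR" in text and "DT" in text and ";" in text

    def test_disjoint_runs_semicolon_separated(self, small_pair):
        dr, _ = small_pair
        text = format_ranges(np.r_[0:5, 50:55], dr)
        assert text.count(";") == 1


class TestFitSpectralModel:
    def test_msc_condition_round_trips_on_new_data(self, small_pair):
        dr, _ = small_pair
        m = fit_spectral_model(
            dr.absorbance[:20], dr.reference[:20], condition="1st der + MSC",
            cv=5,
        )
        preds = m.predict(dr.absorbance[20:])
        assert preds.shape == (10,)
        assert np.isfinite(preds).all()

    def test_serialization_reloads_bit_exact(self, small_pair, tmp_path):
        from nirbran import SpectralModel

        dr, _ = small_pair
        m = fit_spectral_model(dr.absorbance[:20], dr.reference[:20],
                               condition="1st der + MSC", cv=5)
        path = tmp_path / "model.json"
        m.save(path)
        back = SpectralModel.load(path)
        np.testing.assert_array_equal(
            back.predict(dr.absorbance[20:]), m.predict(dr.absorbance[20:])
        )
        assert back.condition == m.condition

    def test_selected_lvs_respect_cap(self, small_pair):
        dr, _ = small_pair
        m = fit_spectral_model(dr.absorbance[:20], dr.reference[:20],
                               condition="SNV", cv=5)
        assert 1 <= m.pls.n_lvs <= 2  # floor(20/10)
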