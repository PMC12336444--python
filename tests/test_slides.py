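"""Slide processing: rendering, segmentation, classification, counting."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctcdx.simulate import (CohortSimConfig, SlideSimConfig, render_images,
                            simulate_cohort, simulate_slides)
from ctcdx.slides import (RuleConfig, SlideSummary, classify_cell,
                          classify_cells, compute_slide_means, count_ctcs,
                          count_ctcs_by_slide, ihc_score, segment_cells)


def _cell_table(cells):
    """cells: list of dicts with x_um, y_um, area_um2 and channel totals."""
    rows = []
    for i, c in enumerate(cells):
        rows.append({"slide_id": "s", "cell_id": f"c{i}",
                     "x_um": c.get("x_um", 50.0), "y_um": c.get("y_um", 50.0),
                     "area_um2": c.get("area_um2", 60.0),
                     "int_dapi": c.get("int_dapi", 1e4),
                     "int_ckmix": c.get("int_ckmix", 1e4),
                     "int_cd45": c.get("int_cd45", 1e2),
                     "int_msln": c.get("int_msln", 1e4)})
    return pd.DataFrame(rows)


NOISELESS = SlideSimConfig(pixel_size=0.5, image_shape=(256, 256), psf_sigma=1.5,
                           background=10.0, poisson_scale=0.0, read_noise_sd=0.0)


class TestRender:
    def test_empty_table_background_only(self):
        img = render_images(pd.DataFrame(), NOISELESS)
        assert img.shape == (4, 256, 256)
        assert np.allclose(img, NOISELESS.background)

    def test_flux_conservation_within_one_percent(self):
        """A noise-free cell's integrated background-subtracted signal equals
        its specified total intensity (PSF convolution conserves flux)."""
        cells = _cell_table([{"x_um": 64.0, "y_um": 64.0, "int_ckmix": 10_000.0}])
        img = render_images(cells, NOISELESS)
        total = (img[1] - NOISELESS.background).sum()
        assert total == pytest.approx(10_000.0, rel=0.01)

    def test_disk_pixel_count_matches_area(self):
        """Segmented pixel count of a rendered disk ~ area / pixel_size^2."""
        area = 80.0
        cfg = SlideSimConfig(pixel_size=0.5, image_shape=(128, 128), psf_sigma=0.0,
                             background=0.0)
        cells = _cell_table([{"x_um": 32.0, "y_um": 32.0, "area_um2": area}])
        img = render_images(cells, cfg)
        npx = int((img[0] > 0).sum())
        assert abs(npx - area / cfg.pixel_size**2) / (area / cfg.pixel_size**2) < 0.10

    def test_overcrowded_slide_raises(self):
        cells = _cell_table([{"x_um": 20 + i, "y_um": 20 + (i % 7), "area_um2": 80.0}
                             for i in range(600)])
        small = SlideSimConfig(pixel_size=0.5, image_shape=(100, 100))
        with pytest.raises(ValueError, match="larger field|density"):
            render_images(cells, small)


class TestSegment:
    def test_three_disjoint_disks_three_records(self):
        cells = _cell_table([
            {"x_um": 30.0, "y_um": 30.0}, {"x_um": 80.0, "y_um": 40.0},
            {"x_um": 50.0, "y_um": 100.0}])
        img = render_images(cells, NOISELESS)
        seg = segment_cells(img, pixel_size=NOISELESS.pixel_size, min_area=10.0)
        assert len(seg) == 3

    def test_area_is_pixel_count_times_pixel_area(self):
        # a 100-pixel square component at 0.5 um/px -> 25 um^2
        img = np.full((4, 64, 64), 10.0)
        img[0, 20:30, 20:30] = 1000.0
        seg = segment_cells(img, pixel_size=0.5, min_area=1.0)
        assert len(seg) == 1
        assert seg["area_um2"].iloc[0] == pytest.approx(25.0)

    def test_recovered_totals_match_specified_within_one_percent(self):
        spec = [{"x_um": 30.0, "y_um": 30.0, "int_ckmix": 5000.0, "int_msln": 8000.0,
                 "int_dapi": 20000.0, "int_cd45": 4000.0},
                {"x_um": 90.0, "y_um": 90.0, "int_ckmix": 12000.0, "int_msln": 3000.0,
                 "int_dapi": 30000.0, "int_cd45": 6000.0}]
        img = render_images(_cell_table(spec), NOISELESS)
        seg = segment_cells(img, pixel_size=NOISELESS.pixel_size,
                            min_area=10.0).sort_values("x_um")
        for row, expected in zip(seg.itertuples(), spec):
            for ch in ("dapi", "ckmix", "cd45", "msln"):
                assert getattr(row, f"int_{ch}") == pytest.approx(
                    expected[f"int_{ch}"], rel=0.01)

    def test_blank_dapi_warns_and_returns_empty(self):
        img = np.zeros((4, 32, 32))
        with pytest.warns(UserWarning, match="blank DAPI"):
            seg = segment_cells(img, pixel_size=0.5)
        assert len(seg) == 0


SLIDE = SlideSummary(n_cells=10, mean_dapi=100.0, mean_ckmix=100.0,
                     mean_cd45=100.0, mean_msln=100.0)


class TestClassifyCell:
    def test_all_gates_satisfied_is_msln_pos_ctc(self):
        cell = pd.Series({"area_um2": 50.0, "int_ckmix": 200.0, "int_msln": 200.0,
                          "int_cd45": 10.0, "int_dapi": 100.0})
        assert classify_cell(cell, SLIDE) == "MSLN_POS_CTC"

    def test_small_nucleus_demotes_to_plain_ctc(self):
        """The 47 um^2 area rule gates only the MSLN-positive call."""
        cell = pd.Series({"area_um2": 40.0, "int_ckmix": 200.0, "int_msln": 200.0,
                          "int_cd45": 10.0, "int_dapi": 100.0})
        assert classify_cell(cell, SLIDE) == "CTC"

    def test_ck_negative_cd45_positive_is_wbc(self):
        cell = pd.Series({"area_um2": 30.0, "int_ckmix": 50.0, "int_msln": 10.0,
                          "int_cd45": 200.0, "int_dapi": 100.0})
        assert classify_cell(cell, SLIDE) == "WBC"

    def test_boundary_equalities(self):
        """Tumor gates are inclusive (>=); the CD45 gate is strict (<)."""
        at_mean = pd.Series({"area_um2": 47.0, "int_ckmix": 100.0, "int_msln": 100.0,
                             "int_cd45": 100.0, "int_dapi": 100.0})
        assert classify_cell(at_mean, SLIDE) == "UNCLASSIFIED"  # cd45 == mean fails <
        below_cd45 = at_mean.copy()
        below_cd45["int_cd45"] = 99.9
        assert classify_cell(below_cd45, SLIDE) == "MSLN_POS_CTC"

    def test_area_flag_extends_to_plain_ctc(self):
        cell = pd.Series({"area_um2": 40.0, "int_ckmix": 200.0, "int_msln": 10.0,
                          "int_cd45": 10.0, "int_dapi": 100.0})
        assert classify_cell(cell, SLIDE, RuleConfig()) == "CTC"
        strict = RuleConfig(apply_area_to_plain_ctc=True)
        assert classify_cell(cell, SLIDE, strict) == "UNCLASSIFIED"


class TestClassifyTable:
    def _random_table(self, rng, n=40):
        return pd.DataFrame({
            "slide_id": "s", "cell_id": [f"c{i}" for i in range(n)],
            "x_um": rng.uniform(0, 100, n), "y_um": rng.uniform(0, 100, n),
            "area_um2": rng.uniform(20, 90, n),
            "int_dapi": rng.lognormal(9, 0.5, n),
            "int_ckmix": rng.lognormal(7, 1.5, n),
            "int_cd45": rng.lognormal(7, 1.5, n),
            "int_msln": rng.lognormal(7, 1.5, n)})

    def test_scale_invariance(self, rng):
        """Multiplying every intensity on a slide by c > 0 changes nothing:
        all gates are relative to slide means."""
        cells = self._random_table(rng)
        base = classify_cells(cells)["called_class"]
        for c in (1e-3, 7.3, 1e4):
            scaled = cells.copy()
            for ch in ("int_dapi", "int_ckmix", "int_cd45", "int_msln"):
                scaled[ch] *= c
            assert (classify_cells(scaled)["called_class"] == base).all()

    def test_exactly_one_label_per_cell(self, rng):
        called = classify_cells(self._random_table(rng, 100))
        assert called["called_class"].isin(
            ["MSLN_POS_CTC", "CTC", "WBC", "UNCLASSIFIED"]).all()
        assert len(called) == 100

    def test_raising_msln_never_demotes(self, rng):
        """Monotonicity: increasing a cell's MSLN intensity cannot remove an
        MSLN_POS_CTC call (the slide mean rises less than the cell value)."""
        cells = self._random_table(rng, 30)
        called = classify_cells(cells)
        pos_idx = called.index[called["called_class"] == "MSLN_POS_CTC"]
        if len(pos_idx) == 0:
            cells.loc[0, ["int_ckmix", "int_msln"]] = 1e6
            cells.loc[0, "int_cd45"] = 1.0
            cells.loc[0, "area_um2"] = 60.0
            called = classify_cells(cells)
            pos_idx = called.index[called["called_class"] == "MSLN_POS_CTC"]
        i = pos_idx[0]
        for factor in (2.0, 10.0, 1e3):
            bumped = cells.copy()
            bumped.loc[i, "int_msln"] *= factor
            assert classify_cells(bumped).loc[i, "called_class"] == "MSLN_POS_CTC"

    def test_missing_column_is_named(self):
        with pytest.raises(KeyError, match="int_msln"):
            classify_cells(pd.DataFrame({"area_um2": [1.0], "int_dapi": [1.0],
                                         "int_ckmix": [1.0], "int_cd45": [1.0]}))


class TestCounting:
    def test_all_wbc_zero_counts(self):
        cells = pd.DataFrame({"called_class": ["WBC"] * 50})
        assert count_ctcs(cells) == (0, 0)

    def test_ctc_count_includes_msln_positive_subset(self):
        cells = pd.DataFrame({"called_class": ["MSLN_POS_CTC"] * 2 + ["CTC"] * 3
                              + ["WBC"] * 100})
        assert count_ctcs(cells) == (2, 5)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from(["MSLN_POS_CTC", "CTC", "WBC", "UNCLASSIFIED"]),
                    min_size=1, max_size=50))
    def test_counts_equal_brute_force_tally(self, labels):
        cells = pd.DataFrame({"called_class": labels})
        m, c = count_ctcs(cells)
        assert m == labels.count("MSLN_POS_CTC")
        assert c == m + labels.count("CTC")
        assert m <= c


class TestEndToEndRecovery:
    def test_exact_count_recovery_noise_free(self):
        """With full capture, well-separated class intensities (>= 4 log-SD)
        and no noise, classification recovers every true count exactly."""
        table, truth = simulate_cohort(CohortSimConfig(n_eoc=6, n_benign=4, seed=21))
        cfg = SlideSimConfig(n_wbc=120, capture_efficiency=1.0, seed=22)
        cells, truth = simulate_slides(table, truth, cfg)
        counts = count_ctcs_by_slide(classify_cells(cells))
        merged = counts.merge(truth.patients, left_on="slide_id",
                              right_on="patient_id")
        assert (merged["msln_ctc_count"] == merged["true_msln_ctc_count"]).all()
        assert (merged["ctc_count"] == merged["true_ctc_count"]).all()


class TestIhcScore:
    @pytest.mark.parametrize("pct,intensity,score", [
        (3, 3, 0),      # <5% bin annihilates
        (80, 3, 12),    # >75% bin x strong
        (30, 2, 4),     # 26-50% bin x moderate
        (5, 1, 1), (25, 1, 1), (26, 1, 2), (75, 2, 6), (100, 3, 12),
    ])
    def test_bin_times_intensity(self, pct, intensity, score):
        assert ihc_score(pct, intensity) == score

    @pytest.mark.parametrize("pct,intensity", [(-1, 1), (101, 1), (50, 4), (50, -1)])
    def test_out_of_range_rejected(self, pct, intensity):
        with pytest.raises(ValueError):
            ihc_score(pct, intensity)


def test_compute_slide_means_matches_brute_force(rng):
    n = 25
    cells = pd.DataFrame({
        "int_dapi": rng.uniform(0, 1e4, n), "int_ckmix": rng.uniform(0, 1e4, n),
        "int_cd45": rng.uniform(0, 1e4, n), "int_msln": rng.uniform(0, 1e4, n)})
    s = compute_slide_means(cells)
    assert s.mean_ckmix == pytest.approx(sum(cells["int_ckmix"]) / n)
    assert s.mean_cd45 == pytest.approx(sum(cells["int_cd45"]) / n)
    with pytest.raises(ValueError, match="no cells"):
        compute_slide_means(cells.iloc[:0])
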