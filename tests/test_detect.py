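import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from stedcount import (EmitterDesign, SimulationConfig, build_spot_table,
                       find_maxima, localize_spot, pairwise_distances,
                       psf_peak_factor, read_intensities, simulate_field)

from .oracles import flood_fill_maxima


class TestFindMaxima:
    def test_constant_image_has_no_maxima(self):
        assert len(find_maxima(np.full((7, 7), 3.0), 1.0)) == 0

    def test_single_spike(self):
        img = np.zeros((9, 9))
        img[4, 4] = 100.0
        df = find_maxima(img, 15.0)
        assert df[["row", "col"]].to_numpy().tolist() == [[4, 4]]
        assert df.prominence.iloc[0] == 100.0

    def test_plateau_reported_once_at_centroid(self):
        img = np.zeros((9, 9))
        img[3:5, 3:5] = 10.0  # 2x2 plateau, centroid (3.5, 3.5) rounds to (4, 4)
        df = find_maxima(img, 5.0)
        assert df[["row", "col"]].to_numpy().tolist() == [[4, 4]]

    def test_saddle_prominence(self):
        # two peaks connected through a saddle of height 4
        img = np.zeros((5, 9))
        img[2, 2] = 10.0
        img[2, 6] = 8.0
        img[2, 3:6] = 4.0
        df = find_maxima(img, 3.0)
        by_pos = {(r.row, r.col): r.prominence for r in df.itertuples()}
        assert by_pos[(2, 2)] == 10.0  # global max: value - min
        assert by_pos[(2, 6)] == 4.0  # 8 - saddle 4

    def test_non_finite_pixels_rejected(self):
        img = np.zeros((5, 5))
        img[2, 2] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            find_maxima(img, 1.0)

    def test_invalid_prominence_rejected(self):
        with pytest.raises(ValueError):
            find_maxima(np.zeros((5, 5)), 0.0)

    def test_ordering_by_row_then_column(self):
        img = np.zeros((9, 9))
        for r, c in [(6, 1), (1, 6), (1, 1)]:
            img[r, c] = 50.0
        coords = find_maxima(img, 10.0)[["row", "col"]].to_numpy().tolist()
        assert coords == sorted(coords)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(img=hnp.arrays(np.int64, (6, 6), elements=st.integers(0, 3)),
           prominence=st.sampled_from([1, 2, 3]))
    def test_matches_flood_fill_oracle(self, img, prominence):
        """Property sweep: accepted-maxima sets equal the exhaustive
        flood-fill prominence oracle on small images."""
        ours = sorted(map(tuple,
                          find_maxima(img.astype(float), prominence)
                          [["row", "col"]].to_numpy()))
        assert ours == flood_fill_maxima(img, prominence)

    def test_matches_oracle_on_random_larger_images(self, rng):
        for _ in range(60):
            img = rng.integers(0, 8, (9, 9)).astype(float)
            prom = int(rng.integers(1, 5))
            ours = sorted(map(tuple,
                              find_maxima(img, prom)[["row", "col"]].to_numpy()))
            assert ours == flood_fill_maxima(img, prom)

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(img=hnp.arrays(np.int64, (8, 8), elements=st.integers(0, 6)))
    def test_raising_prominence_never_adds_maxima(self, img):
        img = img.astype(float)
        prev = None
        for prom in (1, 2, 3, 4):
            cur = set(map(tuple, find_maxima(img, prom)[["row", "col"]].to_numpy()))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_perfect_recall_and_precision_on_clean_field(self, quiet_config):
        """Emitters >= 3x prominence over background at >= 5 fwhm spacing
        are recovered exactly, with no false positives."""
        spacing_nm = 5 * quiet_config.psf_fwhm_quant_nm + 30
        positions = [(300.0 + i * spacing_nm, 300.0 + j * spacing_nm)
                     for i in range(5) for j in range(5)]
        designs = [EmitterDesign(x, y, n_docking_strands=3) for x, y in positions]
        image, _ = simulate_field(designs, quiet_config)
        # peak amplitude ~14 au over background, > 3x the prominence used
        df = find_maxima(image.quantification, 4.0)
        assert len(df) == len(positions)
        found = {(r.row, r.col) for r in df.itertuples()}
        p = quiet_config.pixel_size_nm
        truth = {(round(y / p), round(x / p)) for x, y in positions}
        assert found == truth

    def test_exclude_border_flag(self):
        img = np.zeros((9, 9))
        img[0, 4] = 50.0
        img[4, 4] = 50.0
        assert len(find_maxima(img, 10.0)) == 2
        kept = find_maxima(img, 10.0, exclude_border=True)
        assert kept[["row", "col"]].to_numpy().tolist() == [[4, 4]]


class TestReadIntensities:
    def test_single_pixel_readout(self):
        img = np.arange(25.0).reshape(5, 5)
        img[2, 3] = 7.0
        assert read_intensities(img, [(2, 3)])[0] == 7.0

    def test_empty_coordinates(self):
        assert read_intensities(np.zeros((5, 5)), []).size == 0

    def test_out_of_bounds_names_row(self):
        with pytest.raises(ValueError, match="row 1"):
            read_intensities(np.zeros((5, 5)), [(1, 1), (9, 0)])

    def test_mean3x3_mode(self):
        img = np.zeros((5, 5))
        img[2, 2] = 9.0
        assert read_intensities(img, [(2, 2)], mode="mean3x3")[0] == 1.0

    def test_noise_free_peak_matches_closed_form(self, quiet_config):
        d = EmitterDesign(3000.0, 1500.0, n_docking_strands=2)
        image, truth = simulate_field([d], quiet_config)
        value = read_intensities(image.quantification, [(50, 100)])[0]
        pf = psf_peak_factor(quiet_config.psf_fwhm_quant_nm,
                             quiet_config.pixel_size_nm)
        expected = quiet_config.background + truth.realized_brightness.iloc[0] * pf
        assert value == pytest.approx(expected, rel=1e-9)


class TestLocalize:
    def test_recovers_pixel_centered_spot(self, quiet_config):
        image, _ = simulate_field([EmitterDesign(3000.0, 3000.0)], quiet_config)
        loc = localize_spot(image.quantification, (100, 100), window=9,
                            pixel_size_nm=30.0)
        assert loc.converged
        assert loc.row_px == pytest.approx(100.0, abs=1e-6)
        assert loc.col_px == pytest.approx(100.0, abs=1e-6)
        assert loc.x_nm == pytest.approx(3000.0, abs=1e-3)

    def test_recovers_subpixel_offset(self, quiet_config):
        # emitter shifted +0.3 px in x
        image, _ = simulate_field([EmitterDesign(3009.0, 3000.0)], quiet_config)
        loc = localize_spot(image.quantification, (100, 100), window=9)
        assert loc.converged
        assert loc.col_px == pytest.approx(100.3, abs=0.02)

    def test_flat_window_flagged(self):
        loc = localize_spot(np.full((15, 15), 4.0), (7, 7))
        assert not loc.converged

    def test_window_validation(self):
        with pytest.raises(ValueError):
            localize_spot(np.zeros((9, 9)), (4, 4), window=4)


class TestPairwiseDistances:
    def test_identical_sets_matched(self):
        pts = np.array([[0.0, 0.0], [10.0, 5.0]])
        out = pairwise_distances(pts, pts)
        assert np.all(out.distances_nm == 0.0)

    def test_three_four_five(self):
        out = pairwise_distances([[0.0, 0.0]], [[30.0, 40.0]])
        assert out.distances_nm[0] == pytest.approx(50.0)

    def test_all_pairs_mode(self):
        out = pairwise_distances([[0, 0], [1, 0]], [[0, 0]], mode="all_pairs")
        assert sorted(out.distances_nm) == pytest.approx([0.0, 1.0])

    def test_recovers_origami_design_distance(self):
        """Localized corner-to-center distances on sparse, high-SNR origami
        recover the 30 nm design value within 3 SE."""
        cfg = SimulationConfig(seed=13, noise="none", brightness_cv=0.02,
                               field_size=(300, 300), psf_fwhm_ref_nm=40.0,
                               psf_fwhm_quant_nm=40.0,
                               brightness_per_fluorophore=200.0)
        from stedcount import make_origami_mixture
        image, truth = make_origami_mixture([4], 12, cfg, corner_distance_nm=90.0)
        dists = []
        for oid, group in truth.groupby("origami_id"):
            center = group[group.channel == "quantification"].iloc[0]
            c_loc = localize_spot(image.quantification,
                                  (round(center.y_nm / 30), round(center.x_nm / 30)),
                                  window=7, pixel_size_nm=30.0)
            for corner in group[group.channel == "reference"].itertuples():
                r_loc = localize_spot(image.reference,
                                      (round(corner.y_nm / 30), round(corner.x_nm / 30)),
                                      window=7, pixel_size_nm=30.0)
                if c_loc.converged and r_loc.converged:
                    d = pairwise_distances([[c_loc.x_nm, c_loc.y_nm]],
                                           [[r_loc.x_nm, r_loc.y_nm]])
                    dists.append(d.distances_nm[0])
        dists = np.array(dists)
        assert len(dists) >= 30
        se = dists.std(ddof=1) / np.sqrt(len(dists))
        assert abs(dists.mean() - 90.0) < max(3 * se, 0.5)


def test_build_spot_table_columns(quiet_config):
    image, _ = simulate_field(
        [EmitterDesign(1500.0, 1500.0, channel="reference"),
         EmitterDesign(1500.0, 1500.0)], quiet_config)
    table = build_spot_table(image, prominence=3.0)
    assert list(table.columns) == ["spot_id", "row", "col", "x_px", "y_px",
                                   "x_nm", "y_nm", "I_ref_au", "I_quant_au"]
    assert len(table) == 1
    assert table.x_nm.iloc[0] == 1500.0
    assert table.I_quant_au.iloc[0] > quiet_config.background
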