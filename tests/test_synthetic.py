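"""The generator's ground truth must be exact: it anchors every other test."""

import numpy as np
import pytest

import endoquant as eq


class TestCellImage:
    def test_full_colocalization_at_zero_offset_duplicates_positions(self):
        cfg = eq.SynthImageConfig(
            n_vesicles_per_channel=(10, 10), coloc_fraction=1.0, coloc_offset_nm=0.0
        )
        _, truth = eq.generate_cell_image(cfg)
        a = truth.positions_nm["chA"]
        b = truth.positions_nm["chB"]
        # every channel-B spot coincides with some channel-A spot
        for pb in b:
            assert np.min(np.linalg.norm(a - pb, axis=1)) == pytest.approx(0.0)

    def test_empty_configuration_yields_background_only(self):
        cfg = eq.SynthImageConfig(n_vesicles_per_channel=(0, 0), seed=3)
        stack, truth = eq.generate_cell_image(cfg)
        assert truth.n_spots("chA") == 0 and truth.n_spots("chB") == 0
        # no rendered structure beyond cell body + noise: the max should be
        # far below a spot peak
        assert stack.data.max() < 5 * cfg.cell_level

    def test_same_seed_is_bit_identical(self):
        cfg = eq.SynthImageConfig(coloc_fraction=0.5, seed=11)
        s1, t1 = eq.generate_cell_image(cfg)
        s2, t2 = eq.generate_cell_image(cfg)
        np.testing.assert_array_equal(s1.data, s2.data)
        np.testing.assert_array_equal(
            t1.positions_nm["chB"], t2.positions_nm["chB"]
        )
        assert t1.pairs == t2.pairs

    @pytest.mark.parametrize("fraction", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_imposed_pair_count_is_exact(self, fraction):
        cfg = eq.SynthImageConfig(coloc_fraction=fraction, seed=5)
        _, truth = eq.generate_cell_image(cfg)
        n_b = cfg.n_vesicles_per_channel[1]
        assert len(truth.pairs) == round(fraction * n_b)

    def test_pair_distances_bounded_by_offset(self):
        cfg = eq.SynthImageConfig(
            coloc_fraction=0.5, coloc_offset_nm=250.0, seed=9
        )
        _, truth = eq.generate_cell_image(cfg)
        a = truth.positions_nm["chA"]
        b = truth.positions_nm["chB"]
        for ia, ib in truth.pairs:
            assert np.linalg.norm(a[ia] - b[ib]) <= 250.0 + 1e-9

    def test_all_spots_inside_cell(self):
        cfg = eq.SynthImageConfig(coloc_fraction=0.3, seed=21)
        _, truth = eq.generate_cell_image(cfg)
        cy, cx = truth.cell_center_px
        for ch in ("chA", "chB"):
            pos_px = truth.positions_nm[ch] / cfg.pixel_size_nm
            r = np.hypot(pos_px[:, 0] - cy, pos_px[:, 1] - cx)
            assert np.all(r <= truth.cell_radius_px)

    def test_unpaired_spots_respect_exclusion_radius(self):
        cfg = eq.SynthImageConfig(coloc_fraction=0.5, seed=13)
        _, truth = eq.generate_cell_image(cfg)
        a = truth.positions_nm["chA"]
        b = truth.positions_nm["chB"]
        paired_b = {ib for _, ib in truth.pairs}
        for ib, pb in enumerate(b):
            if ib in paired_b:
                continue
            assert np.min(np.linalg.norm(a - pb, axis=1)) > cfg.exclusion_radius_nm

    def test_infeasible_spot_count_raises(self):
        cfg = eq.SynthImageConfig(
            cell_radius_px=15.0, n_vesicles_per_channel=(60, 0), seed=1
        )
        with pytest.raises(ValueError, match="could not place"):
            eq.generate_cell_image(cfg)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            eq.SynthImageConfig(coloc_fraction=1.5)

    def test_mean_photon_count_matches_configured_intensity(self):
        # Poisson sampling preserves the configured integrated intensity:
        # relative error < 1% with >= 1e4 photons per spot, averaged over spots
        cfg = eq.SynthImageConfig(
            n_vesicles_per_channel=(12, 0),
            spot_intensity=50000.0,
            cell_level=0.0,
            background_level=0.0,
            read_noise_sd=0.0,
            seed=17,
        )
        stack, truth = eq.generate_cell_image(cfg)
        total = stack.data[0, 0].sum()
        expected = 12 * cfg.spot_intensity
        assert abs(total - expected) / expected < 0.01


class TestTirfSeries:
    def test_label_counts_follow_rate(self):
        cfg = eq.SynthImageConfig(image_size_px=(256, 256))
        for rate, want in [(1.0, 20), (0.0, 0), (0.5, 10)]:
            _, truth = eq.generate_tirf_series(cfg, 20, rate, 12, seed=2)
            assert truth.cofusion_labels.sum() == want

    def test_too_few_frames_rejected(self):
        cfg = eq.SynthImageConfig()
        with pytest.raises(ValueError, match="n_frames"):
            eq.generate_tirf_series(cfg, 5, 0.5, n_frames=3, seed=0)

    def test_cargo_decays_and_noncofusion_marker_persists(self):
        cfg = eq.SynthImageConfig(
            image_size_px=(256, 256), spot_intensity=20000.0, seed=4
        )
        stack, truth = eq.generate_tirf_series(cfg, 20, 0.5, 12, seed=4)
        params = eq.FusionParams()
        for i, (pos_nm, win) in enumerate(
            zip(truth.positions_nm["events"], truth.event_windows)
        ):
            pos = tuple(pos_nm / cfg.pixel_size_nm)
            cargo = eq.extract_event_trace(stack, "cargo", pos, win, params)
            marker = eq.extract_event_trace(stack, "marker", pos, win, params)
            # cargo always collapses
            assert cargo.max_intensity[-1] < 0.5 * cargo.max_intensity[0]
            if not truth.cofusion_labels[i]:
                # persisting marker: drop well below the 10% criterion scale
                drop = (
                    marker.max_intensity[0] - marker.max_intensity[-3:].mean()
                ) / marker.max_intensity[0]
                assert drop < 0.10

    def test_determinism(self):
        cfg = eq.SynthImageConfig(image_size_px=(128, 128))
        s1, t1 = eq.generate_tirf_series(cfg, 8, 0.5, 10, seed=6)
        s2, t2 = eq.generate_tirf_series(cfg, 8, 0.5, 10, seed=6)
        np.testing.assert_array_equal(s1.data, s2.data)
        np.testing.assert_array_equal(t1.cofusion_labels, t2.cofusion_labels)


class TestGroupedTimeseries:
    def test_zero_effect_has_no_true_divergence(self):
        _, truth = eq.generate_grouped_timeseries(
            10, np.arange(6.0), 3, 0.0, 1.0, seed=0
        )
        assert truth.divergence_index is None

    def test_shift_applies_from_start_index_onward(self):
        series, truth = eq.generate_grouped_timeseries(
            500, np.arange(6.0), 2, 5.0, 0.01, seed=1
        )
        assert truth.divergence_index == 2
        for i in range(6):
            gap = np.median(series.samples_a[i]) - np.median(series.samples_b[i])
            if i >= 2:
                assert gap == pytest.approx(5.0, abs=0.1)
            else:
                assert gap == pytest.approx(0.0, abs=0.1)

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            eq.generate_grouped_timeseries(0, np.arange(4.0), 1, 1.0, 1.0)

    def test_shift_index_bounds_checked(self):
        with pytest.raises(ValueError):
            eq.generate_grouped_timeseries(5, np.arange(4.0), 4, 1.0, 1.0)
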