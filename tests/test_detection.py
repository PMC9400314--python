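"""Spot detection, cell segmentation and linking against constructed truths."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

import endoquant as eq
from endoquant.detection import DetectionParams, NoCellFoundError

from conftest import make_stack


def gaussian_spot(shape, cy, cx, sigma=1.5, integral=2000.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    g = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))
    return g * integral / (2 * np.pi * sigma**2)


class TestSegmentCell:
    def test_blank_image_raises(self):
        stack = make_stack(np.zeros((64, 64)))
        with pytest.raises(NoCellFoundError):
            eq.segment_cell(stack, 0, 0)

    def test_disk_area_recovered_within_5_percent(self):
        cfg = eq.SynthImageConfig(
            image_size_px=(140, 140), cell_radius_px=50.0, seed=8
        )
        stack, _ = eq.generate_cell_image(cfg)
        cell = eq.segment_cell(stack, 0, 0)
        assert abs(cell.area_px - np.pi * 50**2) / (np.pi * 50**2) < 0.05

    def test_symmetric_cell_centroid_within_half_pixel(self):
        cfg = eq.SynthImageConfig(
            image_size_px=(140, 140),
            cell_radius_px=50.0,
            n_vesicles_per_channel=(0, 0),
            seed=8,
        )
        stack, truth = eq.generate_cell_image(cfg)
        cell = eq.segment_cell(stack, 0, 0)
        assert abs(cell.intensity_centroid_px[0] - truth.cell_center_px[0]) < 0.5
        assert abs(cell.intensity_centroid_px[1] - truth.cell_center_px[1]) < 0.5


class TestDetectVesicles:
    def test_blank_frame_gives_no_detections(self):
        stack = make_stack(np.zeros((64, 64)))
        assert len(eq.detect_vesicles(stack, 0, 0)) == 0

    def test_ten_spots_at_snr10_all_found_within_one_pixel(self, snr10_config):
        import dataclasses

        cfg = dataclasses.replace(
            snr10_config, n_vesicles_per_channel=(10, 0), seed=23
        )
        stack, truth = eq.generate_cell_image(cfg)
        det = eq.detect_vesicles(stack, 0, 0)
        assert len(det) == 10
        d, _ = cKDTree(truth.positions_nm["chA"] / cfg.pixel_size_nm).query(
            det.positions_px()
        )
        assert np.all(d < 1.0)

    def test_close_pair_merges_to_weighted_midpoint(self):
        img = gaussian_spot((64, 64), 30.0, 30.0, integral=3000.0)
        img += gaussian_spot((64, 64), 30.0, 32.0, integral=3000.0)
        stack = make_stack(img + 1.0)
        det = eq.detect_vesicles(
            stack, 0, 0, DetectionParams(min_separation_px=4.0)
        )
        assert len(det) == 1
        # equal-intensity pair: midpoint at x = 31
        assert det.table.loc[0, "y_px"] == pytest.approx(30.0, abs=0.3)
        assert det.table.loc[0, "x_px"] == pytest.approx(31.0, abs=0.3)

    def test_sorted_by_descending_peak(self):
        img = gaussian_spot((96, 96), 20.0, 20.0, integral=1000.0)
        img += gaussian_spot((96, 96), 70.0, 70.0, integral=5000.0)
        img += gaussian_spot((96, 96), 20.0, 70.0, integral=3000.0)
        stack = make_stack(img + 1.0)
        det = eq.detect_vesicles(stack, 0, 0)
        peaks = det.table["peak_intensity"].to_numpy()
        assert np.all(np.diff(peaks) <= 0)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        img = np.full((96, 96), 10.0)
        for cy, cx in [(30, 40), (60, 25), (70, 66)]:
            img += gaussian_spot((96, 96), cy, cx, integral=4000.0)
        shifted = np.roll(np.roll(img, 5, axis=0), -3, axis=1)
        d0 = eq.detect_vesicles(make_stack(img), 0, 0)
        d1 = eq.detect_vesicles(make_stack(shifted), 0, 0)
        assert len(d0) == len(d1) == 3
        p0 = np.sort(d0.positions_px(), axis=0)
        p1 = np.sort(d1.positions_px() - [5, -3], axis=0)
        np.testing.assert_allclose(p0, p1, atol=1e-6)

    def test_no_duplicates_within_min_separation(self, snr10_config):
        import dataclasses

        for seed in range(3):
            cfg = dataclasses.replace(snr10_config, coloc_fraction=0.5, seed=seed)
            stack, _ = eq.generate_cell_image(cfg)
            det = eq.detect_vesicles(stack, 1, 0)
            pos = det.positions_px()
            if len(pos) > 1:
                d, _ = cKDTree(pos).query(pos, k=2)
                assert np.all(d[:, 1] >= 4.0)

    def test_localization_rmse_below_half_pixel(self, snr10_config):
        import dataclasses

        errs = []
        for seed in range(5):
            cfg = dataclasses.replace(snr10_config, seed=seed)
            stack, truth = eq.generate_cell_image(cfg)
            det = eq.detect_vesicles(stack, 0, 0)
            d, _ = cKDTree(det.positions_px()).query(
                truth.positions_nm["chA"] / cfg.pixel_size_nm
            )
            errs.extend(d[d < 2.0])
        assert np.sqrt(np.mean(np.square(errs))) < 0.5


class TestCounting:
    def test_blank_movie_counts_zero(self):
        stack = make_stack(np.zeros((3, 1, 64, 64)))
        counts = eq.count_vesicles_over_time(stack, 0)
        assert counts["count"].tolist() == [0, 0, 0]

    def test_cumulative_generator_counts_ramp(self):
        cfg = eq.SynthImageConfig(
            n_vesicles_per_channel=(5, 0),
            n_frames=5,
            cumulative_spots=True,
            seed=31,
        )
        stack, _ = eq.generate_cell_image(cfg)
        counts = eq.count_vesicles_over_time(stack, 0)
        assert counts["count"].tolist() == [1, 2, 3, 4, 5]
        np.testing.assert_allclose(counts["time_s"], np.arange(5.0))

    def test_counts_invariant_under_intensity_scaling(self):
        cfg = eq.SynthImageConfig(n_vesicles_per_channel=(8, 0), seed=19)
        stack, _ = eq.generate_cell_image(cfg)
        scaled = eq.FrameStack(
            stack.data * 7.3,
            stack.pixel_size_nm,
            stack.frame_interval_s,
            list(stack.channel_names),
        )
        c0 = eq.count_vesicles_over_time(stack, 0)["count"].tolist()
        c1 = eq.count_vesicles_over_time(scaled, 0)["count"].tolist()
        assert c0 == c1


def detections_from_points(points_by_frame):
    import pandas as pd

    rows = []
    for frame, pts in points_by_frame.items():
        for y, x in pts:
            rows.append(
                {
                    "frame": frame,
                    "channel": "ch0",
                    "y_px": y,
                    "x_px": x,
                    "y_nm": y * 100,
                    "x_nm": x * 100,
                    "peak_intensity": 1.0,
                    "integrated_intensity": 1.0,
                }
            )
    return eq.VesicleSet(pd.DataFrame(rows))


class TestLinking:
    def test_stationary_spot_forms_one_track(self):
        det = detections_from_points({t: [(30.0, 30.0)] for t in range(10)})
        tracks = eq.link_tracks(det)
        assert len(tracks) == 1
        assert len(tracks[0]) == 10
        assert np.all(np.diff(tracks[0].frames) == 1)

    def test_excessive_displacement_terminates_tracks(self):
        # two spots swap positions across 20 px; the gate (5 px) must
        # terminate both tracks rather than swap identities
        det = detections_from_points(
            {0: [(10.0, 10.0), (10.0, 30.0)], 1: [(10.0, 30.0), (10.0, 10.0)]}
        )
        # mutual NN would link (10,10)->(10,10)? distances: spot0@f0 to f1:
        # 20 and 0 -> nearest is the same position; that is a 0-px move, OK.
        # Construct a true over-gate case: both move 20 px with no overlap.
        det = detections_from_points(
            {0: [(10.0, 10.0), (10.0, 40.0)], 1: [(10.0, 22.0), (10.0, 52.0)]}
        )
        tracks = eq.link_tracks(
            det, DetectionParams(max_link_displacement_px=5.0)
        )
        assert len(tracks) == 4
        assert all(len(t) == 1 for t in tracks)

    def test_matches_optimal_assignment_when_unambiguous(self):
        rng = np.random.default_rng(7)
        pts0 = rng.uniform(10, 90, size=(5, 2))
        moves = rng.uniform(-1.5, 1.5, size=(5, 2))
        pts1 = pts0 + moves
        det = detections_from_points(
            {0: [tuple(p) for p in pts0], 1: [tuple(p) for p in pts1]}
        )
        tracks = eq.link_tracks(det, DetectionParams(max_link_displacement_px=5.0))
        # oracle: minimal-total-displacement assignment
        dmat = np.linalg.norm(pts0[:, None] - pts1[None], axis=2)
        ri, ci = linear_sum_assignment(dmat)
        optimal = dict(zip(ri, ci))
        assert len(tracks) == 5
        for t in tracks:
            assert len(t) == 2
            p0 = t.vesicles.iloc[0][["y_px", "x_px"]].to_numpy(dtype=float)
            p1 = t.vesicles.iloc[1][["y_px", "x_px"]].to_numpy(dtype=float)
            i = int(np.argmin(np.linalg.norm(pts0 - p0, axis=1)))
            j = int(np.argmin(np.linalg.norm(pts1 - p1, axis=1)))
            assert optimal[i] == j

    def test_each_track_has_strictly_increasing_frames(self):
        rng = np.random.default_rng(3)
        pts = {t: [tuple(p) for p in rng.uniform(5, 90, size=(4, 2))] for t in range(4)}
        tracks = eq.link_tracks(detections_from_points(pts))
        for t in tracks:
            assert np.all(np.diff(t.frames) > 0)
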