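"""Localization, linking, gap interpolation and static extension."""

import numpy as np
import pandas as pd
import pytest

from chondrotrace.stack import ImageStack
from chondrotrace.tracking import (
    DETECTED,
    EXTENDED,
    INTERPOLATED,
    CellTracks,
    TrackParams,
    composite,
    extend_static,
    interpolate_gaps,
    link,
    locate,
    track,
)


def _tracks(rows):
    return CellTracks(pd.DataFrame(rows, columns=CellTracks.COLUMNS))


def _gauss(shape, x0, y0, amp=20.0, sigma=2.0, background=5.0):
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    return background + amp * np.exp(
        -((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2)
    )


class TestComposite:
    def test_sum_of_uniform_channels(self):
        data = np.zeros((1, 3, 8, 8), dtype=np.float32)
        data[0, 0], data[0, 1], data[0, 2] = 1, 2, 3
        assert np.all(composite(ImageStack(data), 0) == 6)

    def test_empty_channel_drops_out(self):
        data = np.zeros((1, 3, 8, 8), dtype=np.float32)
        data[0, 0], data[0, 2] = 4, 1
        assert np.all(composite(ImageStack(data), 0) == 5)

    def test_equals_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 10, (3, 3, 16, 16)).astype(np.float32)
        stack = ImageStack(data)
        np.testing.assert_allclose(composite(stack, 1), data[1].sum(axis=0))

    def test_out_of_range_frame(self):
        stack = ImageStack(np.zeros((2, 3, 8, 8), dtype=np.float32))
        with pytest.raises(IndexError):
            composite(stack, 5)


class TestLocate:
    def test_blank_image(self):
        assert len(locate(np.full((64, 64), 3.0))) == 0

    def test_subpixel_accuracy_on_single_spot(self):
        img = _gauss((256, 256), 100.0, 200.0)
        det = locate(img, TrackParams())
        assert len(det) == 1
        assert abs(det.iloc[0]["x"] - 100.0) < 0.1
        assert abs(det.iloc[0]["y"] - 200.0) < 0.1

    def test_two_well_separated_spots(self):
        img = _gauss((256, 256), 100, 100) + _gauss((256, 256), 150, 100,
                                                    background=0.0)
        det = locate(img, TrackParams())
        assert len(det) == 2

    def test_min_mass_filters_dim_spot(self):
        img = _gauss((128, 128), 64, 64, amp=0.5)
        assert len(locate(img, TrackParams(min_mass=40.0))) == 0

    def test_even_diameter_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            TrackParams(locate_diameter=8)

    def test_negative_image_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            locate(np.full((32, 32), -1.0))


class TestLink:
    def test_static_spot_single_track(self):
        det = pd.DataFrame({"frame": range(10), "x": [50.0] * 10, "y": [60.0] * 10})
        tracks = link(det, TrackParams())
        assert tracks.n_tracks == 1
        assert len(tracks.df) == 10
        assert set(tracks.df["provenance"]) == {DETECTED}

    def test_opposite_drifts_keep_identities(self):
        frames, xs, ys = [], [], []
        for t in range(20):
            frames += [t, t]
            xs += [50.0 + t, 150.0 - t]
            ys += [50.0, 50.0]
        tracks = link(pd.DataFrame({"frame": frames, "x": xs, "y": ys}),
                      TrackParams())
        assert tracks.n_tracks == 2
        for _, g in tracks.df.groupby("cell_id"):
            dx = np.diff(g["x"].to_numpy())
            assert np.all(dx == 1.0) or np.all(dx == -1.0)

    def test_jump_beyond_limit_starts_new_track(self):
        det = pd.DataFrame({
            "frame": [0, 1, 2, 3],
            "x": [10.0, 10.0, 60.0, 60.0],
            "y": [10.0, 10.0, 10.0, 10.0],
        })
        tracks = link(det, TrackParams(max_link_displacement=5.0,
                                       max_gap_frames=0))
        assert tracks.n_tracks == 2

    def test_empty_input(self):
        assert len(link(pd.DataFrame(columns=["frame", "x", "y"]))) == 0

    def test_memory_bridges_missing_frames(self):
        det = pd.DataFrame({
            "frame": [0, 1, 4, 5],
            "x": [10.0, 10.2, 10.8, 11.0],
            "y": [5.0] * 4,
        })
        tracks = link(det, TrackParams(max_gap_frames=3))
        assert tracks.n_tracks == 1


class TestInterpolateGaps:
    def test_midpoint_interpolation(self):
        tracks = _tracks([
            (0, 5, 10.0, 0.0, DETECTED),
            (0, 7, 12.0, 0.0, DETECTED),
        ])
        out = interpolate_gaps(tracks, TrackParams())
        g = out.for_cell(0)
        mid = g[g["frame"] == 6]
        assert len(mid) == 1
        assert mid.iloc[0]["x"] == 11.0
        assert mid.iloc[0]["y"] == 0.0
        assert mid.iloc[0]["provenance"] == INTERPOLATED

    def test_large_gap_displacement_splits_track(self):
        tracks = _tracks([
            (0, 0, 0.0, 0.0, DETECTED),
            (0, 1, 1.0, 0.0, DETECTED),
            (0, 4, 31.0, 0.0, DETECTED),
        ])
        out = interpolate_gaps(tracks, TrackParams(max_gap_displacement=10.0))
        assert out.n_tracks == 2
        assert INTERPOLATED not in set(out.df["provenance"])

    def test_gapless_track_unchanged(self):
        tracks = _tracks([(3, t, float(t), 0.0, DETECTED) for t in range(5)])
        out = interpolate_gaps(tracks, TrackParams())
        pd.testing.assert_frame_equal(out.df, tracks.df)

    def test_interpolated_points_collinear(self):
        tracks = _tracks([
            (0, 0, 1.0, 2.0, DETECTED),
            (0, 5, 6.0, 9.5, DETECTED),
        ])
        out = interpolate_gaps(tracks, TrackParams())
        g = out.for_cell(0)
        p0 = np.array([1.0, 2.0])
        p1 = np.array([6.0, 9.5])
        seg = p1 - p0
        for _, row in g.iterrows():
            v = np.array([row["x"], row["y"]]) - p0
            cross = seg[0] * v[1] - seg[1] * v[0]
            assert abs(cross) < 1e-9


class TestExtendStatic:
    def test_extends_to_final_frame_at_last_position(self):
        tracks = _tracks([(0, t, 5.0, 6.0, DETECTED) for t in range(101)])
        out = extend_static(tracks, 300, TrackParams(static_start_frame=50))
        g = out.for_cell(0)
        assert len(g) == 300
        tail = g[g["frame"] >= 101]
        assert set(tail["provenance"]) == {EXTENDED}
        assert np.all(tail["x"] == 5.0)
        assert np.all(tail["y"] == 6.0)

    def test_full_span_track_unchanged(self):
        tracks = _tracks([(0, t, 1.0, 1.0, DETECTED) for t in range(10)])
        out = extend_static(tracks, 10, TrackParams(static_start_frame=0))
        pd.testing.assert_frame_equal(out.df, tracks.df)

    def test_extension_off_is_identity(self):
        tracks = _tracks([(0, t, 1.0, 1.0, DETECTED) for t in range(5)])
        out = extend_static(tracks, 20, TrackParams(static_extension=False))
        pd.testing.assert_frame_equal(out.df, tracks.df)

    def test_track_ending_before_static_phase_not_extended(self):
        tracks = _tracks([(0, t, 1.0, 1.0, DETECTED) for t in range(5)])
        out = extend_static(tracks, 100, TrackParams(static_start_frame=50))
        assert len(out.for_cell(0)) == 5

    def test_static_start_beyond_stack_errors(self):
        tracks = _tracks([(0, 0, 1.0, 1.0, DETECTED)])
        with pytest.raises(ValueError, match="beyond"):
            extend_static(tracks, 10, TrackParams(static_start_frame=50))


class TestFullTracking:
    def test_empty_stack(self):
        stack = ImageStack(np.zeros((3, 3, 64, 64), dtype=np.float32))
        assert len(track(stack)) == 0

    def test_static_scene_recovers_all_cells(self, small_static_scene,
                                             small_static_stack):
        """Noise-free static scene: >= 99% of cells become single
        full-length tracks with localization RMSE < 0.5 px."""
        scene, stack = small_static_scene, small_static_stack
        tracks = track(stack, TrackParams())
        T = scene.params.frame_count
        full = {cid: g for cid, g in tracks.df.groupby("cell_id") if len(g) == T}
        n_recovered = 0
        sq_err = []
        for cell in scene.cells:
            best = None
            for cid, g in full.items():
                err = np.hypot(
                    g["x"].to_numpy() - cell.trajectory[g["frame"], 0],
                    g["y"].to_numpy() - cell.trajectory[g["frame"], 1],
                )
                if best is None or err.mean() < best[0]:
                    best = (err.mean(), err)
            if best is not None and best[0] < 2.0:
                n_recovered += 1
                sq_err.append(best[1] ** 2)
        assert n_recovered >= 0.99 * scene.n_cells
        rmse = float(np.sqrt(np.concatenate(sq_err).mean()))
        assert rmse < 0.5

    def test_provenance_counts_conserve_track_length(self, small_static_stack):
        tracks = track(small_static_stack, TrackParams())
        tracks.validate()
        for cid, g in tracks.df.groupby("cell_id"):
            prov = g["provenance"].value_counts()
            assert (
                prov.get(DETECTED, 0)
                + prov.get(INTERPOLATED, 0)
                + prov.get(EXTENDED, 0)
                == len(g)
            )

    def test_dropout_scene_mostly_fully_tracked(self):
        """With 5% per-frame detection dropout, the interpolation and
        static-extension stages recover full tracks for the large majority
        of cells (full coverage is bounded by frame-0 dropout survival,
        ~95% in expectation)."""
        from chondrotrace.synth import (
            RenderParams, ScenarioParams, make_scene, render_stack,
        )
        from chondrotrace.tracking import locate_all

        p = ScenarioParams(n_cells=40, frame_count=150, field_size=256,
                           noise_sd=1.0, seed=21)
        scene = make_scene(p)
        stack = render_stack(scene, RenderParams(camera_noise_sd=0.5))
        params = TrackParams()
        det = locate_all(stack, params)
        rng = np.random.default_rng(22)
        det = det[rng.random(len(det)) >= 0.05]
        tracks = extend_static(
            interpolate_gaps(link(det, params), params), p.frame_count, params
        )
        full = [g for _, g in tracks.df.groupby("cell_id")
                if len(g) == p.frame_count]
        n_recovered = 0
        for cell in scene.cells:
            for g in full:
                err = np.hypot(
                    g["x"].to_numpy() - cell.trajectory[g["frame"], 0],
                    g["y"].to_numpy() - cell.trajectory[g["frame"], 1],
                ).mean()
                if err < 2.0:
                    n_recovered += 1
                    break
        assert n_recovered >= 0.85 * p.n_cells
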