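"""Parameter scaling, boundary-box placement and frame-to-frame tracking."""

import numpy as np
import pytest

from centrotrack.engine import (
    PixelSizes,
    SeedPair,
    default_params,
    make_boundary_box,
    scale_params,
    track_centrosome,
    track_pair,
)
from centrotrack.movie import EmbryoGeometry, Movie
from centrotrack.simulate import SyntheticSpec, generate_movie, suite_spec


GEOM = EmbryoGeometry(embryo_height=232, resolution=0.129)


class TestScaleParams:
    def test_base_sizes_at_relative_one(self):
        # 232 px embryo (~30 µm at 0.129 µm/px): hbb = 4% -> 9 px,
        # dsc = 12% -> 28 px rounded to odd
        sizes = scale_params(default_params("anterior", hbb_rel=1.0, dsc_rel=1.0), GEOM)
        assert sizes.hbb == 9
        assert sizes.wbb == 5
        assert sizes.dsc in (27, 29) and sizes.dsc % 2 == 1
        assert sizes.gc == 3

    def test_optimized_defaults(self):
        ant = scale_params(default_params("anterior"), GEOM)
        post = scale_params(default_params("posterior"), GEOM)
        assert ant.hbb == round(1.125 * 0.04 * 232)
        assert post.hbb == round(1.375 * 0.04 * 232)
        assert ant.dsc % 2 == 1 and post.dsc % 2 == 1

    def test_framerate_multiplier_scales_hbb_threefold(self):
        # at a 3x lower acquisition frequency hbb must triple
        geom = EmbryoGeometry(embryo_height=200, resolution=0.129)
        base = scale_params(default_params("anterior", hbb_rel=1.0), geom)
        slow = scale_params(
            default_params("anterior", hbb_rel=1.0, framerate_multiplier=3.0), geom
        )
        assert base.hbb == 8
        assert slow.hbb == 3 * base.hbb

    def test_minimum_sizes_enforced(self):
        tiny = EmbryoGeometry(embryo_height=20, resolution=0.129)
        sizes = scale_params(default_params("anterior", hbb_rel=0.5, dsc_rel=0.5), tiny)
        assert sizes.hbb >= 3 and sizes.wbb >= 1 and sizes.dsc >= 3 and sizes.gc >= 3

    def test_oversized_window_raises(self):
        with pytest.raises(ValueError, match="exceed"):
            scale_params(default_params("anterior"), GEOM, frame_shape=(20, 20))


class TestBoundaryBox:
    SIZES = PixelSizes(hbb=9, wbb=5, dsc=29, gc=3)

    def test_posterior_backward_shifts_two_thirds_anteriorward(self):
        params = default_params("posterior")  # backward by default
        box = make_boundary_box((100, 50), params, self.SIZES, (200, 200))
        assert (box.y_min, box.y_max) == (46, 54)
        # 2/3 of the width on the left (anterior) side of x=100
        assert (box.x_min, box.x_max) == (97, 101)

    def test_anterior_forward_equals_posterior_backward_shift(self):
        # both expect anteriorward (leftward) motion in their tracked
        # direction of time, so the shift side coincides
        a = make_boundary_box((100, 50), default_params("anterior"), self.SIZES, (200, 200))
        p = make_boundary_box((100, 50), default_params("posterior"), self.SIZES, (200, 200))
        assert (a.x_min, a.x_max) == (p.x_min, p.x_max) == (97, 101)

    def test_flipping_direction_mirrors_shift(self):
        fwd = make_boundary_box((100, 50), default_params("anterior"), self.SIZES, (200, 200))
        bwd = make_boundary_box(
            (100, 50), default_params("anterior", direction="backward"), self.SIZES, (200, 200)
        )
        assert 100 - fwd.x_min == bwd.x_max - 100
        assert fwd.x_max - 100 == 100 - bwd.x_min

    def test_clipped_at_frame_corner_remains_nonempty(self):
        box = make_boundary_box((2, 2), default_params("anterior"), self.SIZES, (200, 200))
        assert box.x_min >= 0 and box.y_min >= 0
        assert box.width >= 1 and box.height >= 1

    def test_symmetric_split(self):
        box = make_boundary_box(
            (100, 50), default_params("anterior", box_split=0.5), self.SIZES, (200, 200)
        )
        assert (box.x_min, box.x_max) == (98, 102)


def _seed_for(params, truth, role):
    sp = truth.seed_pair(role)
    return sp.first_frame_position if params.direction == "forward" else sp.last_frame_position


class TestTracking:
    def test_static_disc_tracked_within_one_pixel(self):
        spec = SyntheticSpec(
            n_frames=50,
            posterior_ap_drift=0.0,
            anterior_ap_drift=0.0,
            posterior_osc_amp_um=0.0,
            anterior_osc_amp_um=0.0,
            seed=3,
        )
        movie, truth = generate_movie(spec)
        for role in ("anterior", "posterior"):
            # scanning circle matched to the simulated centrosome size
            params = default_params(role, dsc_rel=1.0)
            track = track_centrosome(movie, _seed_for(params, truth, role), params, spec.geometry)
            err = np.abs(track.positions - truth.positions(role))
            assert err.max() <= 1

    def test_slow_horizontal_motion_tracked_closely(self):
        # ~1 px/frame drift toward the posterior
        spec = SyntheticSpec(
            n_frames=40,
            posterior_ap_start=15.0,
            posterior_ap_drift=40.0,
            drift_tau_frames=10.0,
            posterior_osc_amp_um=0.0,
            anterior_osc_amp_um=0.0,
            seed=4,
        )
        movie, truth = generate_movie(spec)
        params = default_params("posterior")
        track = track_centrosome(movie, _seed_for(params, truth, "posterior"), params, spec.geometry)
        err = np.linalg.norm(track.positions - truth.positions("posterior"), axis=1)
        assert np.median(err) <= 1.5
        assert err.max() <= 3

    def test_per_frame_displacement_bounded_by_box(self, suite_movie_0):
        spec, movie, truth = suite_movie_0
        for role in ("anterior", "posterior"):
            params = default_params(role)
            sizes = scale_params(params, spec.geometry)
            track = track_centrosome(movie, _seed_for(params, truth, role), params, spec.geometry)
            step = np.abs(np.diff(track.positions, axis=0))
            assert step[:, 0].max() <= sizes.wbb
            assert step[:, 1].max() <= sizes.hbb // 2 + 1

    def test_tracking_is_deterministic(self, suite_movie_0):
        spec, movie, truth = suite_movie_0
        params = default_params("anterior")
        seed = _seed_for(params, truth, "anterior")
        t1 = track_centrosome(movie, seed, params, spec.geometry)
        t2 = track_centrosome(movie, seed, params, spec.geometry)
        assert t1.entries == t2.entries

    def test_reversal_with_symmetric_split_is_exact(self, small_movie):
        spec, movie, truth = small_movie
        reversed_movie = Movie(movie.frames[::-1].copy(), movie.resolution, movie.frame_interval)
        for role in ("anterior", "posterior"):
            params = default_params(role, box_split=0.5)
            track = track_centrosome(movie, _seed_for(params, truth, role), params, spec.geometry)
            opposite = "backward" if params.direction == "forward" else "forward"
            rev_params = default_params(role, box_split=0.5, direction=opposite)
            sp = truth.seed_pair(role)
            rev_seed = (
                sp.first_frame_position if opposite == "backward" else sp.last_frame_position
            )
            rev_track = track_centrosome(reversed_movie, rev_seed, rev_params, spec.geometry)
            assert np.array_equal(track.positions, rev_track.positions[::-1])

    def test_jump_beyond_box_cannot_be_followed(self):
        # documented contract: per-frame reach is bounded by the box, so a
        # teleporting disc is lost
        spec = SyntheticSpec(n_frames=6, posterior_osc_amp_um=0.0, anterior_osc_amp_um=0.0,
                             posterior_ap_drift=0.0, anterior_ap_drift=0.0, seed=5)
        movie, truth = generate_movie(spec)
        frames = movie.frames.copy()
        frames[3:] = np.roll(frames[3:], 60, axis=2)  # 60 px jump
        jumped = Movie(frames, movie.resolution, movie.frame_interval)
        params = default_params("anterior")
        sizes = scale_params(params, spec.geometry)
        track = track_centrosome(movie, _seed_for(params, truth, "anterior"), params, spec.geometry)
        jumped_track = track_centrosome(
            jumped, _seed_for(params, truth, "anterior"), params, spec.geometry
        )
        step = np.abs(np.diff(jumped_track.positions, axis=0))
        assert step[:, 0].max() <= sizes.wbb  # cannot jump 60 px in one frame
        assert track is not jumped_track

    def test_short_movie_raises(self):
        movie = Movie(np.zeros((1, 50, 50), dtype=np.uint8))
        with pytest.raises(ValueError, match="2 frames"):
            track_centrosome(movie, (25, 25), default_params("anterior"),
                             EmbryoGeometry(embryo_height=40))


class TestTrackPair:
    def test_defaults_and_coverage(self, small_movie):
        spec, movie, truth = small_movie
        seeds = {r: truth.seed_pair(r) for r in ("anterior", "posterior")}
        ant, post = track_pair(movie, seeds, spec.geometry)
        assert ant.params.direction == "forward" and ant.params.hbb_rel == 1.125
        assert post.params.direction == "backward" and post.params.dsc_rel == 1.125
        assert np.array_equal(ant.frame_indices, post.frame_indices)

    def test_direction_override_is_honored(self, small_movie):
        spec, movie, truth = small_movie
        seeds = {r: truth.seed_pair(r) for r in ("anterior", "posterior")}
        _, post = track_pair(
            movie, seeds, spec.geometry,
            params={"posterior": default_params("posterior", direction="forward")},
        )
        assert post.direction == "forward"

    def test_two_static_discs_both_tracked(self):
        spec = SyntheticSpec(n_frames=20, posterior_ap_drift=0.0, anterior_ap_drift=0.0,
                             posterior_osc_amp_um=0.0, anterior_osc_amp_um=0.0, seed=6)
        movie, truth = generate_movie(spec)
        seeds = {r: truth.seed_pair(r) for r in ("anterior", "posterior")}
        matched = {r: default_params(r, dsc_rel=1.0) for r in ("anterior", "posterior")}
        ant, post = track_pair(movie, seeds, spec.geometry, params=matched)
        assert np.abs(ant.positions - truth.positions("anterior")).max() <= 1
        assert np.abs(post.positions - truth.positions("posterior")).max() <= 1

    def test_bad_seed_error_names_role(self, small_movie):
        spec, movie, truth = small_movie
        seeds = {
            "anterior": SeedPair((-5, -5), (-5, -5)),
            "posterior": truth.seed_pair("posterior"),
        }
        with pytest.raises(RuntimeError, match="anterior"):
            track_pair(movie, seeds, spec.geometry)
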