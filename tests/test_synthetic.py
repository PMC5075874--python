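"""Generator properties: geometry, determinism, non-overlap, ground truth."""

import math

import numpy as np
import pytest
from scipy import ndimage

from wormchip.synthetic import (
    ClusterSpec,
    DeadDarknessCurve,
    SceneSpec,
    expected_shape_area,
    generate_assay_timelapse,
    generate_worm_shape,
    render_scene,
)

EIGHT = np.ones((3, 3), dtype=bool)


class TestWormShape:
    def test_straight_rod_area_within_tube_bounds(self):
        mask, _ = generate_worm_shape(100, 10, curvature_amplitude=0.0, seed=0,
                                      base_angle=0.0)
        assert 850 <= mask.sum() <= 1150

    @pytest.mark.parametrize("seed", range(5))
    def test_single_connected_component(self, seed):
        mask, _ = generate_worm_shape(100, 10, curvature_amplitude=0.4, seed=seed)
        _, n = ndimage.label(mask, structure=EIGHT)
        assert n == 1

    def test_sinusoidal_area_matches_swept_tube_prediction(self):
        # oracle: closed-form area of the radius profile integrated over length
        predicted = expected_shape_area(120, 8)
        areas = []
        for seed in range(5):
            mask, _ = generate_worm_shape(120, 8, curvature_amplitude=0.35, seed=seed)
            areas.append(mask.sum())
        ratio = np.mean(areas) / predicted
        assert 0.85 <= ratio <= 1.15

    def test_midline_spans_requested_length(self):
        mask, midline = generate_worm_shape(100, 10, 0.3, seed=3)
        seg = np.linalg.norm(np.diff(midline, axis=0), axis=1).sum()
        assert 90 <= seg <= 110

    def test_rejects_stubby_geometry(self):
        with pytest.raises(ValueError):
            generate_worm_shape(30, 10, 0.2, seed=0)


class TestRenderScene:
    def test_empty_scene_has_no_labels(self):
        spec = SceneSpec(n_worms=0, image_height_px=128, image_width_px=128, seed=1)
        bf, fl, gt = render_scene(spec)
        assert gt.label_image.max() == 0
        assert bf.pixels.shape == (128, 128)

    def test_label_pixel_count_matches_per_worm_areas(self, pair_scene):
        _, _, _, gt = pair_scene
        assert (gt.label_image > 0).sum() == sum(w.area_px for w in gt.worms)

    def test_worms_never_overlap(self, pair_scene):
        # every nonzero label pixel belongs to exactly one worm by
        # construction; check areas are consistent under re-rendering
        spec, _, _, gt = pair_scene
        areas = np.bincount(gt.label_image.ravel())[1:]
        assert (areas > 0).all() and len(areas) == spec.n_worms

    def test_side_touch_pair_is_one_component_two_labels(self, pair_scene):
        _, _, _, gt = pair_scene
        union = (gt.label_image == 1) | (gt.label_image == 2)
        _, n = ndimage.label(union, structure=EIGHT)
        assert n == 1
        assert set(np.unique(gt.label_image[union])) == {1, 2}

    def test_nonmember_worms_stay_separate(self, pair_scene):
        _, _, _, gt = pair_scene
        for wid in range(3, 8):
            grown = ndimage.binary_dilation(gt.label_image == wid, EIGHT)
            others = (gt.label_image > 0) & (gt.label_image != wid)
            assert not (grown & others).any()

    def test_determinism_bit_identical(self):
        spec = SceneSpec(n_worms=4, seed=99)
        a = render_scene(spec)
        b = render_scene(spec)
        assert np.array_equal(a[0].pixels, b[0].pixels)
        assert np.array_equal(a[1].pixels, b[1].pixels)
        assert np.array_equal(a[2].label_image, b[2].label_image)

    def test_dead_worm_fainter_than_alive(self):
        spec = SceneSpec(n_worms=2, seed=5, noise_sd=0.0)
        _, _, gt_alive = render_scene(spec)
        bf_dead, _, gt_dead = render_scene(spec, hours_since_death=[6.0, None])
        dark = bf_dead.darkness
        dead_mean = dark[gt_dead.label_image == 1].mean()
        alive_mean = dark[gt_dead.label_image == 2].mean()
        assert dead_mean < alive_mean - 0.3
        assert not gt_dead.worms[0].alive and gt_dead.worms[1].alive

    def test_midpoint_threshold_recovers_live_worm_pixels(self):
        # noiseless scene: thresholding at the alive/background midpoint must
        # recover >= 99% of ground-truth worm pixels
        spec = SceneSpec(n_worms=5, seed=8, noise_sd=0.0)
        bf, _, gt = render_scene(spec)
        mid = (spec.background_level + spec.alive_darkness) / 2
        mask = bf.darkness > mid
        truth = gt.label_image > 0
        recall = (mask & truth).sum() / truth.sum()
        assert recall >= 0.99

    def test_fluorescence_deposits_requested_totals(self):
        spec = SceneSpec(n_worms=2, seed=11, noise_sd=0.0,
                         fluor_per_worm=(30.0, 80.0), fluor_background=0.02)
        _, fl, gt = render_scene(spec)
        for w in gt.worms:
            got = (fl.pixels[gt.label_image == w.worm_id] - 0.02).sum()
            assert got == pytest.approx(w.fluorescence_total, rel=0.02)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SceneSpec(worm_width_px=(25.0, 1.0))  # not elongated
        with pytest.raises(ValueError):
            SceneSpec(alive_darkness=0.05, background_level=0.08)
        with pytest.raises(ValueError):
            ClusterSpec((0, 1), "hug")


class TestDeadDarknessCurve:
    def test_monotone_decay_toward_background(self):
        curve = DeadDarknessCurve(half_life_h=1.0)
        vals = [curve(t, 0.65, 0.08) for t in (0, 1, 2, 4, 8)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert vals[0] == 0.65
        assert vals[-1] == pytest.approx(0.08, abs=0.01)


class TestTimelapse:
    def test_death_flag_flips_after_death_hour(self):
        spec = SceneSpec(n_worms=3, seed=2, image_height_px=256, image_width_px=256)
        frames = generate_assay_timelapse(
            spec, [10.0, math.inf, math.inf], n_frames=13, render_pairs=False
        )
        alive_course = [af.truth[0].worms[0].alive for af in frames]
        assert alive_course[10] and not alive_course[11]
        assert all(af.truth[0].worms[1].alive for af in frames)

    def test_immortal_worms_constant_count_and_darkness(self):
        spec = SceneSpec(n_worms=3, seed=4, image_height_px=256, image_width_px=256,
                         noise_sd=0.0)
        frames = generate_assay_timelapse(
            spec, [math.inf] * 3, n_frames=4, render_pairs=False
        )
        for af in frames:
            assert len(af.truth[0].worms) == 3
            dark = af.brightfield[0].darkness
            for w in af.truth[0].worms:
                assert dark[af.truth[0].label_image == w.worm_id].mean() > 0.4

    def test_zero_speed_pair_frames_identical_at_worm_pixels(self):
        spec = SceneSpec(n_worms=2, seed=6, image_height_px=256, image_width_px=256,
                         noise_sd=0.0)
        frames = generate_assay_timelapse(
            spec, [math.inf, math.inf], n_frames=2, speeds_px=[0.0, 0.0]
        )
        af = frames[0]
        assert np.array_equal(af.truth[0].label_image, af.truth[1].label_image)

    def test_moving_worms_displace_between_pair_frames(self):
        spec = SceneSpec(n_worms=2, seed=6, image_height_px=256, image_width_px=256)
        frames = generate_assay_timelapse(
            spec, [math.inf, math.inf], n_frames=1, speeds_px=[5.0, 5.0]
        )
        af = frames[0]
        assert not np.array_equal(af.truth[0].label_image, af.truth[1].label_image)

    def test_rejects_mismatched_death_times(self):
        spec = SceneSpec(n_worms=2, seed=1)
        with pytest.raises(ValueError):
            generate_assay_timelapse(spec, [1.0], n_frames=2)
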