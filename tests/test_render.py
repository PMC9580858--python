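import numpy as np
import pytest
from dataclasses import replace

import voxcast as vc
from voxcast.errors import InvalidParameterError
from _oracles import oracle_render, oracle_trilinear
from conftest import random_rotation


def plain_settings(**kw):
    kw.setdefault("overlays", vc.OverlaySettings(plane_grid=False, coordinate_readout=False))
    return vc.RenderSettings(**kw)


class TestSampleChannels:
    def test_value_at_voxel_center(self, small_volume):
        # centres sit at index + 0.5
        got = vc.sample_channels(small_volume, (2.5, 3.5, 4.5))
        expect = small_volume.codes[:, 4, 3, 2] / 255.0
        assert got == pytest.approx(expect, abs=0)

    def test_midpoint_is_mean(self, small_volume):
        got = vc.sample_channels(small_volume, (3.0, 3.5, 4.5))
        expect = (small_volume.codes[:, 4, 3, 2].astype(float)
                  + small_volume.codes[:, 4, 3, 3]) / 2.0 / 255.0
        assert got == pytest.approx(expect, abs=1e-12)

    def test_outside_is_zero(self, small_volume):
        assert vc.sample_channels(small_volume, (-5.0, 4.0, 4.0)) == pytest.approx([0.0, 0.0])

    def test_matches_corner_sum_oracle(self, small_volume, rng):
        norm = small_volume.codes.astype(np.float64) / 255.0
        for _ in range(50):
            p = rng.uniform(-0.5, 8.5, size=3)
            got = vc.sample_channels(small_volume, p)
            expect = oracle_trilinear(norm, small_volume.meta.dims, p)
            assert got == pytest.approx(expect, abs=1e-12)


class TestCompositeStep:
    def test_opaque_first_sample_occludes(self):
        acc = vc.composite_step((np.zeros(3), 0.0), ((0.2, 0.9, 0.1), 1.0))
        assert acc[0] == pytest.approx([0.2, 0.9, 0.1])
        assert acc[1] == 1.0
        acc2 = vc.composite_step(acc, ((1.0, 1.0, 1.0), 1.0))
        assert acc2[0] == pytest.approx(acc[0])
        assert acc2[1] == 1.0

    def test_two_half_alpha_samples(self):
        # over-operator by hand: C = 0.5*1 + 0.5*0.5*0 = 0.5; a = 0.5 + 0.5*0.5
        acc = vc.composite_step((np.zeros(3), 0.0), ((1.0, 1.0, 1.0), 0.5))
        acc = vc.composite_step(acc, ((0.0, 0.0, 0.0), 0.5))
        assert acc[0] == pytest.approx([0.5, 0.5, 0.5])
        assert acc[1] == pytest.approx(0.75)

    def test_transparent_noop(self):
        acc = vc.composite_step(((0.3, 0.1, 0.2), 0.4), ((1.0, 1.0, 1.0), 0.0))
        assert acc[0] == pytest.approx([0.3, 0.1, 0.2])
        assert acc[1] == pytest.approx(0.4)


class TestChannelBlend:
    def test_single_channel(self):
        t = vc.ChannelTransfer(alpha=0.8, color=(0.0, 0.5, 1.0))
        rgb, a = vc.channel_blend([0.5], [t])
        e = vc.apply_transfer(t, 0.5)
        assert a == pytest.approx(e * 0.8)
        assert rgb == pytest.approx([0.0, 0.5, 1.0])

    def test_two_equal_channels_red_green(self):
        # a_1 = a_2 = 0.5: alpha = 1 - 0.25 = 0.75, colour = (0.5, 0.5, 0)
        red = vc.ChannelTransfer(i_dark=0.0, i_mid=0.5, i_bright=0.5, alpha=0.5, color=(1, 0, 0))
        green = vc.ChannelTransfer(i_dark=0.0, i_mid=0.5, i_bright=0.5, alpha=0.5, color=(0, 1, 0))
        rgb, a = vc.channel_blend([0.9, 0.9], [red, green])  # both fully emissive
        assert a == pytest.approx(0.75)
        assert rgb == pytest.approx([0.5, 0.5, 0.0])

    def test_below_dark_is_transparent(self):
        ts = [vc.ChannelTransfer(i_dark=0.3, i_bright=0.9, color=c)
              for c in [(1, 0, 0), (0, 1, 0)]]
        rgb, a = vc.channel_blend([0.2, 0.3], ts)
        assert a == 0.0
        assert rgb == pytest.approx([0.0, 0.0, 0.0])

    def test_invisible_channel_skipped(self):
        ts = [vc.ChannelTransfer(color=(1, 0, 0)),
              vc.ChannelTransfer(color=(0, 1, 0), visible=False)]
        rgb, a = vc.channel_blend([1.0, 1.0], ts)
        assert rgb == pytest.approx([1.0, 0.0, 0.0])
        assert a == pytest.approx(1.0)


class TestRenderFrame:
    def test_all_zero_volume_is_exact_background(self):
        vol = vc.Volume(meta=vc.VolumeMetadata(dims=(8, 8, 8), num_channels=1),
                        codes=np.zeros((1, 8, 8, 8)))
        cam = vc.CameraModel(viewport=(16, 16))
        settings = vc.RenderSettings(background=(0.1, 0.2, 0.3))
        frame = vc.render_frame(vol, vc.default_transfers(1), vc.ViewParams(), cam, settings)
        assert np.all(frame.rgb == np.array([0.1, 0.2, 0.3]))
        assert np.all(frame.alpha == 0.0)

    def test_single_voxel_pure_red_and_miss_is_background(self, probe_volume):
        cam = vc.CameraModel(viewport=(33, 33))
        transfers = [vc.ChannelTransfer(i_dark=0.0, i_bright=0.3, color=(1, 0, 0))]
        settings = plain_settings(background=(0.0, 0.0, 1.0))
        frame = vc.render_frame(probe_volume, transfers, vc.ViewParams(), cam, settings)
        # centre pixel's ray passes exactly through the probe voxel centre
        assert frame.rgb[16, 16] == pytest.approx([1.0, 0.0, 0.0], abs=1e-12)
        # corner ray misses the box entirely
        assert frame.rgb[0, 0] == pytest.approx([0.0, 0.0, 1.0], abs=0)

    def test_matches_oracle_integrator(self, rng):
        vol = vc.make_synthetic_volume("blobs", dims=(8, 8, 8), num_channels=2, seed=21)
        cam = vc.CameraModel(viewport=(16, 16))
        transfers = [
            vc.ChannelTransfer(i_dark=0.1, i_mid=0.65, i_bright=0.8, alpha=0.9, color=(1, 0, 0)),
            vc.ChannelTransfer(i_dark=0.0, i_mid=0.4, i_bright=0.9, alpha=0.7, color=(0, 1, 0)),
        ]
        settings = plain_settings(background=(0.05, 0.05, 0.1))
        view = vc.ViewParams(world_rotation=random_rotation(rng), zoom=1.3)
        frame = vc.render_frame(vol, transfers, view, cam, settings)
        expect_rgb, expect_a = oracle_render(vol, transfers, view, cam, settings)
        assert np.abs(frame.rgb - expect_rgb).max() < 1e-9
        assert np.abs(frame.alpha - expect_a).max() < 1e-9

    def test_alpha_bounded_and_channel_symmetry(self, rng):
        vol = vc.make_synthetic_volume("blobs", dims=(8, 8, 8), num_channels=2, seed=4)
        cam = vc.CameraModel(viewport=(12, 12))
        transfers = [
            vc.ChannelTransfer(i_dark=0.1, i_bright=0.7, color=(1, 0, 0)),
            vc.ChannelTransfer(i_dark=0.2, i_bright=0.9, color=(0, 0, 1)),
        ]
        view = vc.ViewParams(world_rotation=random_rotation(rng))
        frame = vc.render_frame(vol, transfers, view, cam, plain_settings())
        assert frame.alpha.max() <= 1.0 and frame.alpha.min() >= 0.0
        # permute channels with their transfers
        permuted = vc.Volume(meta=vol.meta, codes=vol.codes[::-1].copy(),
                             norm_records=vol.norm_records[::-1])
        frame2 = vc.render_frame(permuted, transfers[::-1], view, cam, plain_settings())
        assert np.abs(frame.rgb - frame2.rgb).max() < 1e-12

    def test_occlusion_content_behind_saturating_wall(self):
        # Opaque wall on the camera-side z-layers; edits behind it are invisible.
        meta = vc.VolumeMetadata(dims=(9, 9, 9), num_channels=1)
        codes = np.zeros((1, 9, 9, 9), dtype=np.uint8)
        codes[0, 6:, :, :] = 255  # high z = closer to camera
        transfers = [vc.ChannelTransfer(i_dark=0.0, i_bright=0.5, color=(1, 1, 1))]
        cam = vc.CameraModel(viewport=(15, 15))
        before = vc.render_frame(vc.Volume(meta=meta, codes=codes.copy()), transfers,
                                 vc.ViewParams(), cam, plain_settings())
        codes[0, :3, :, :] = 200  # strictly behind the wall
        after = vc.render_frame(vc.Volume(meta=meta, codes=codes), transfers,
                                vc.ViewParams(), cam, plain_settings())
        assert np.array_equal(before.rgb, after.rgb)

    def test_front_clip_limits(self, small_volume):
        cam = vc.CameraModel(viewport=(12, 12))
        transfers = vc.default_transfers(2)
        settings = plain_settings(background=(0.3, 0.0, 0.0))
        off = vc.render_frame(small_volume, transfers,
                              vc.ViewParams(clip_mode="off"), cam, settings)
        # plane on the camera side of the whole box: everything is behind it
        front_all = vc.render_frame(small_volume, transfers,
                                    vc.ViewParams(clip_mode="front", plane_depth=5.0),
                                    cam, settings)
        assert np.array_equal(off.rgb, front_all.rgb)
        # plane beyond the far side: nothing is behind it
        front_none = vc.render_frame(small_volume, transfers,
                                     vc.ViewParams(clip_mode="front", plane_depth=-5.0),
                                     cam, settings)
        assert np.all(front_none.rgb == np.array([0.3, 0.0, 0.0]))

    def test_early_termination_threshold_validated(self):
        with pytest.raises(InvalidParameterError):
            vc.RenderSettings(early_termination_alpha=0.0)


class TestRenderSlice:
    def test_requires_plane_mode(self, small_volume):
        cam = vc.CameraModel(viewport=(8, 8))
        with pytest.raises(InvalidParameterError):
            vc.render_slice(small_volume, vc.default_transfers(2), vc.ViewParams(), cam)

    def test_equals_render_frame_in_plane_mode(self, small_volume):
        cam = vc.CameraModel(viewport=(16, 16))
        view = vc.ViewParams(clip_mode="plane", plane_depth=0.05)
        transfers = vc.default_transfers(2)
        a = vc.render_slice(small_volume, transfers, view, cam, plain_settings())
        b = vc.render_frame(small_volume, transfers, view, cam, plain_settings())
        assert np.abs(a.rgb - b.rgb).max() <= 1e-12

    def test_plane_outside_box_is_background(self, small_volume):
        cam = vc.CameraModel(viewport=(8, 8))
        settings = plain_settings(background=(0.0, 0.4, 0.0))
        view = vc.ViewParams(clip_mode="plane", plane_depth=3.0)
        frame = vc.render_slice(small_volume, vc.default_transfers(2), view, cam, settings)
        assert np.all(frame.rgb == np.array([0.0, 0.4, 0.0]))

    def test_matches_direct_slice_extraction(self):
        # Axis-aligned slice through z = k: aim a 1x1-viewport ray straight
        # down the view axis through each voxel centre and compare with a
        # transfer-mapped read of the raw slice.
        vol = vc.make_synthetic_volume("blobs", dims=(6, 6, 6), num_channels=1, seed=9)
        transfers = [vc.ChannelTransfer(i_dark=0.0, i_mid=0.6, i_bright=0.9, color=(0, 1, 0))]
        ext = vc.volume_world_box(vol.meta)
        k = 2
        cam = vc.CameraModel(viewport=(1, 1))
        for iy in range(6):
            for ix in range(6):
                center = (np.array([ix, iy, k]) + 0.5) / 6.0 * ext - ext / 2.0
                view = vc.ViewParams(clip_mode="plane", plane_depth=center[2],
                                     pan=(center[0], center[1]))
                frame = vc.render_slice(vol, transfers, view, cam, plain_settings())
                value = vol.codes[0, k, iy, ix] / 255.0
                e = vc.apply_transfer(transfers[0], value)
                assert frame.rgb[0, 0] == pytest.approx([0.0, e, 0.0], abs=1e-9)

    def test_opaque_slice_ignores_content_behind(self):
        meta = vc.VolumeMetadata(dims=(7, 7, 7), num_channels=1)
        codes = np.full((1, 7, 7, 7), 255, dtype=np.uint8)
        vol = vc.Volume(meta=meta, codes=codes)
        transfers = [vc.ChannelTransfer(i_dark=0.0, i_bright=0.5, color=(1, 0, 0))]
        cam = vc.CameraModel(viewport=(9, 9))
        view = vc.ViewParams(clip_mode="plane", plane_depth=0.0)
        frame = vc.render_slice(vol, transfers, view, cam, plain_settings())
        codes2 = codes.copy()
        codes2[0, :2] = 0  # behind the slice plane
        frame2 = vc.render_slice(vc.Volume(meta=meta, codes=codes2), transfers, view, cam,
                                 plain_settings())
        assert np.array_equal(frame.rgb, frame2.rgb)


class TestOverlays:
    def test_grid_changes_frame_only_when_plane_engaged(self, small_volume):
        cam = vc.CameraModel(viewport=(32, 32))
        transfers = vc.default_transfers(2)
        on = vc.RenderSettings(overlays=vc.OverlaySettings(True, True))
        off_set = vc.RenderSettings(overlays=vc.OverlaySettings(False, False))
        view_front = vc.ViewParams(clip_mode="front", plane_depth=0.0)
        with_overlay = vc.render_frame(small_volume, transfers, view_front, cam, on)
        without = vc.render_frame(small_volume, transfers, view_front, cam, off_set)
        assert not np.array_equal(with_overlay.rgb, without.rgb)
        # clip off: sampling plane not engaged, overlays not drawn
        view_off = vc.ViewParams(clip_mode="off")
        a = vc.render_frame(small_volume, transfers, view_off, cam, on)
        b = vc.render_frame(small_volume, transfers, view_off, cam, off_set)
        assert np.array_equal(a.rgb, b.rgb)

    def test_grid_pixels_are_yellow(self, small_volume):
        cam = vc.CameraModel(viewport=(48, 48))
        view = vc.ViewParams(clip_mode="front", plane_depth=0.0)
        settings = vc.RenderSettings(
            overlays=vc.OverlaySettings(plane_grid=True, coordinate_readout=False))
        frame = vc.render_frame(small_volume, vc.default_transfers(2), view, cam, settings)
        yellow = np.all(frame.rgb == np.array([1.0, 1.0, 0.0]), axis=-1)
        assert yellow.any()


class TestPngRoundTrip:
    def test_lossless_and_deterministic(self, small_volume, session_factory):
        s = session_factory(small_volume, viewport=(24, 24))
        png1 = s.capture()
        png2 = s.capture()
        assert png1 == png2
        arr = vc.png_bytes_to_array(png1)
        assert arr.shape == (24, 24, 3)
        frame = s.render()
        expect = np.floor(frame.rgb * 255.0 + 0.5).astype(np.uint8)
        assert np.array_equal(arr, expect)
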