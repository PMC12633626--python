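"""Stroked-mask rule, color modes, and alpha compositing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from matplotlib import colormaps

import ftumask as fm
from ftumask.errors import BoundsError, DimensionError, StyleError

from conftest import naive_stroked_mask, random_label_plane


def block_plane(outer: int, inner: int) -> np.ndarray:
    """An ``inner``x``inner`` block of 1s centered in an ``outer`` plane."""
    p = np.zeros((outer, outer), dtype=np.int64)
    off = (outer - inner) // 2
    p[off : off + inner, off : off + inner] = 1
    return p


class TestStrokedMask:
    @pytest.mark.parametrize(
        "outer, inner, width",
        [(5, 3, 1), (7, 5, 1), (7, 5, 2), (9, 5, 3), (64, 30, 4)],
    )
    def test_block_examples_match_per_pixel_reference(self, outer, inner, width):
        """Centered blocks at several stroke widths match the 8-lookup oracle."""
        p = block_plane(outer, inner)
        got = fm.stroked_mask(p, width)
        assert np.array_equal(got, naive_stroked_mask(p, width))

    def test_five_block_width_one_strokes_the_perimeter_ring(self):
        p = block_plane(7, 5)
        s = fm.stroked_mask(p, 1)
        # 16 perimeter pixels of the block are stroked, inner 3x3 is not
        assert int(s.sum()) == 16
        assert not s[2:5, 2:5].any()

    def test_block_centers_are_not_stroked(self):
        """A centered block's middle pixel sees only its own value at every
        lookup, so it stays un-stroked: 8 of 9 pixels for a 3x3 block at
        width 1, 24 of 25 for a 5x5 block at width 2."""
        s3 = fm.stroked_mask(block_plane(5, 3), 1)
        assert int(s3.sum()) == 8 and not s3[2, 2]
        s5 = fm.stroked_mask(block_plane(7, 5), 2)
        assert int(s5.sum()) == 24 and not s5[3, 3]

    def test_background_is_never_stroked(self):
        p = block_plane(9, 3)
        s = fm.stroked_mask(p, 2)
        assert not s[p == 0].any()

    def test_border_touching_instance_is_outlined(self):
        p = np.ones((5, 5), dtype=np.int64)  # instance fills the plane
        s = fm.stroked_mask(p, 1)
        # out-of-bounds reads background, so the frame strokes
        assert s[0].all() and s[-1].all() and s[:, 0].all() and s[:, -1].all()
        assert not s[2, 2]

    def test_adjacent_instances_stroke_their_shared_boundary(self):
        p = np.zeros((4, 6), dtype=np.int64)
        p[:, :3] = 1
        p[:, 3:] = 2
        s = fm.stroked_mask(p, 1)
        assert s[:, 2].all() and s[:, 3].all()

    def test_stroked_equals_filled_for_small_disks(self):
        """Instances with diameter <= 2*strokeWidth are entirely stroked."""
        for w in (1, 2, 3):
            spec = fm.SynthSpec(
                shape=(64, 64),
                types=[fm.TypeSpec("d", 6, "disk", (0.5, float(w) - 0.01))],
                seed=w,
            )
            ds, _ = fm.generate_dataset(spec)
            plane = ds.bitmask["d"].plane
            assert np.array_equal(fm.stroked_mask(plane, w), plane > 0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        size=st.integers(4, 48),
        n_blobs=st.integers(1, 5),
        width=st.integers(1, 5),
    )
    def test_vectorized_equals_naive_reference(self, seed, size, n_blobs, width):
        rng = np.random.default_rng(seed)
        plane = random_label_plane(rng, (size, size), n_blobs)
        assert np.array_equal(
            fm.stroked_mask(plane, width), naive_stroked_mask(plane, width)
        )

    def test_invalid_stroke_width(self):
        with pytest.raises(StyleError):
            fm.stroked_mask(np.zeros((3, 3), dtype=np.int64), 0)


class TestRenderChannel:
    def _channel(self):
        p = np.zeros((6, 6), dtype=np.int64)
        p[1:3, 1:3] = 1
        p[4:6, 4:6] = 2
        return fm.BitmaskChannel("ptc", p)

    def test_static_mode_exact_rgba(self):
        ch = self._channel()
        style = fm.ChannelStyle(mode="static", static_color=(255, 0, 0), opacity=1.0)
        r = fm.render_channel(ch, style)
        on = ch.plane > 0
        assert (r[on] == [255, 0, 0, 255]).all()
        assert (r[~on, 3] == 0).all()

    def test_opacity_scales_alpha(self):
        ch = self._channel()
        style = fm.ChannelStyle(mode="static", static_color=(0, 255, 0), opacity=0.4)
        r = fm.render_channel(ch, style)
        assert (r[ch.plane > 0, 3] == round(0.4 * 255)).all()

    def test_invisible_channel_is_fully_transparent(self):
        ch = self._channel()
        style = fm.ChannelStyle(is_visible=False, mode="static",
                                static_color=(255, 0, 0))
        assert not fm.render_channel(ch, style).any()

    def test_stroked_mode_colors_only_stroked_pixels(self):
        p = block_plane(7, 5)
        ch = fm.BitmaskChannel("t", p)
        style = fm.ChannelStyle(mode="static", static_color=(0, 0, 255),
                                is_filled=False, stroke_width=1)
        r = fm.render_channel(ch, style)
        stroked = fm.stroked_mask(p, 1)
        assert (r[stroked, 3] == 255).all()
        assert (r[~stroked, 3] == 0).all()

    def test_set_mode_maps_instances_through_sets(self):
        ch = self._channel()
        style = fm.ChannelStyle(
            mode="set",
            set_colors={10: (255, 0, 0), 20: (0, 0, 255)},
            instance_sets={1: 10, 2: 20},
        )
        r = fm.render_channel(ch, style)
        assert (r[ch.plane == 1, :3] == [255, 0, 0]).all()
        assert (r[ch.plane == 2, :3] == [0, 0, 255]).all()

    def test_set_mode_unmapped_instance_is_transparent(self):
        ch = self._channel()
        style = fm.ChannelStyle(
            mode="set", set_colors={10: (255, 0, 0)}, instance_sets={1: 10}
        )
        r = fm.render_channel(ch, style)
        assert (r[ch.plane == 2] == 0).all()
        assert (r[ch.plane == 1, 3] == 255).all()

    def test_set_mode_empty_map_is_style_error(self):
        with pytest.raises(StyleError):
            fm.render_channel(self._channel(), fm.ChannelStyle(mode="set"))

    def test_feature_mode_empty_vector_is_style_error(self):
        with pytest.raises(StyleError):
            fm.render_channel(self._channel(), fm.ChannelStyle(mode="feature"))

    def test_feature_mode_min_max_hit_colormap_endpoints(self):
        ch = self._channel()
        for cmap in ("viridis", "magma"):
            style = fm.ChannelStyle(
                mode="feature", feature_values={1: 3.0, 2: 9.0},
                colormap_name=cmap,
            )
            r = fm.render_channel(ch, style)
            lo = np.round(np.array(colormaps[cmap](0.0)[:3]) * 255).astype(np.uint8)
            hi = np.round(np.array(colormaps[cmap](1.0)[:3]) * 255).astype(np.uint8)
            assert (r[ch.plane == 1, :3] == lo).all()
            assert (r[ch.plane == 2, :3] == hi).all()

    def test_feature_mode_constant_vector_maps_to_midpoint(self):
        ch = self._channel()
        style = fm.ChannelStyle(mode="feature", feature_values={1: 5.0, 2: 5.0})
        r = fm.render_channel(ch, style)
        mid = np.round(np.array(colormaps["viridis"](0.5)[:3]) * 255).astype(np.uint8)
        assert (r[ch.plane > 0, :3] == mid).all()

    def test_feature_mode_range_window_rescales_and_clamps(self):
        ch = self._channel()
        # window [0.5, 1.0]: normalized 0 clamps to colormap 0, normalized
        # 1 maps to (1 - 0.5) / 0.5 = 1
        style = fm.ChannelStyle(
            mode="feature", feature_values={1: 0.0, 2: 10.0},
            colormap_range_start=0.5, colormap_range_end=1.0,
        )
        r = fm.render_channel(ch, style)
        lo = np.round(np.array(colormaps["viridis"](0.0)[:3]) * 255).astype(np.uint8)
        hi = np.round(np.array(colormaps["viridis"](1.0)[:3]) * 255).astype(np.uint8)
        assert (r[ch.plane == 1, :3] == lo).all()
        assert (r[ch.plane == 2, :3] == hi).all()

    def test_feature_mode_absent_instance_is_transparent(self):
        ch = self._channel()
        style = fm.ChannelStyle(mode="feature", feature_values={1: 1.0})
        r = fm.render_channel(ch, style)
        assert (r[ch.plane == 2] == 0).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"colormap_range_start": 0.8, "colormap_range_end": 0.2},
            {"colormap_range_start": 0.5, "colormap_range_end": 0.5},
            {"stroke_width": 0},
            {"opacity": 1.5},
            {"mode": "rainbow"},
            {"colormap_name": "jet"},
        ],
    )
    def test_invalid_style_raises(self, kwargs):
        with pytest.raises(StyleError):
            fm.render_channel(self._channel(), fm.ChannelStyle(**kwargs))


def scalar_composite(base, rgba_layers):
    """Per-pixel scalar reference for straight-alpha 'over' compositing."""
    h, w = base.shape[:2]
    out = np.zeros((h, w, 4), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            rgb = [base[r, c, k] / 255.0 for k in range(3)]
            for layer in rgba_layers:
                a = layer[r, c, 3] / 255.0
                rgb = [
                    layer[r, c, k] / 255.0 * a + rgb[k] * (1 - a) for k in range(3)
                ]
            out[r, c, :3] = [round(min(max(v, 0.0), 1.0) * 255) for v in rgb]
            out[r, c, 3] = 255
    return out


class TestComposite:
    def _base(self, n=8):
        rng = np.random.default_rng(0)
        return rng.integers(0, 256, size=(n, n, 3), dtype=np.uint8)

    def test_no_layers_is_identity(self):
        base = self._base()
        tile = fm.composite(base, [])
        assert np.array_equal(tile.rgba[..., :3], base)
        assert (tile.rgba[..., 3] == 255).all()

    def test_all_zero_opacity_equals_base(self):
        base = self._base()
        p = np.zeros((8, 8), dtype=np.int64)
        p[2:6, 2:6] = 1
        mask = fm.MultiChannelBitmask([fm.BitmaskChannel("g", p)])
        cfg = fm.LayerConfig(
            {"g": fm.ChannelStyle(mode="static", static_color=(255, 0, 0),
                                  opacity=0.0)}
        )
        tile = fm.composite(base, [(mask, cfg)])
        assert np.array_equal(tile.rgba[..., :3], base)

    def test_opaque_static_channel_replaces_instance_pixels(self):
        base = self._base()
        p = np.zeros((8, 8), dtype=np.int64)
        p[2:6, 2:6] = 1
        mask = fm.MultiChannelBitmask([fm.BitmaskChannel("g", p)])
        cfg = fm.LayerConfig(
            {"g": fm.ChannelStyle(mode="static", static_color=(255, 0, 0))}
        )
        tile = fm.composite(base, [(mask, cfg)])
        assert (tile.rgba[p > 0, :3] == [255, 0, 0]).all()
        assert np.array_equal(tile.rgba[p == 0, :3], base[p == 0])

    def test_overlapping_channels_match_scalar_reference(self):
        base = self._base()
        p1 = np.zeros((8, 8), dtype=np.int64)
        p1[1:6, 1:6] = 1
        p2 = np.zeros((8, 8), dtype=np.int64)
        p2[3:8, 3:8] = 2
        mask = fm.MultiChannelBitmask(
            [fm.BitmaskChannel("a", p1), fm.BitmaskChannel("b", p2)]
        )
        s1 = fm.ChannelStyle(mode="static", static_color=(255, 0, 0), opacity=0.5)
        s2 = fm.ChannelStyle(mode="static", static_color=(0, 0, 255), opacity=0.5)
        cfg = fm.LayerConfig({"a": s1, "b": s2})
        tile = fm.composite(base, [(mask, cfg)])
        ref = scalar_composite(
            base,
            [fm.render_channel(mask["a"], s1), fm.render_channel(mask["b"], s2)],
        )
        assert np.array_equal(tile.rgba, ref)

    def test_layer_opacity_multiplies_channel_alpha(self):
        base = np.full((4, 4, 3), 0, dtype=np.uint8)
        p = np.ones((4, 4), dtype=np.int64)
        mask = fm.MultiChannelBitmask([fm.BitmaskChannel("g", p)])
        cfg = fm.LayerConfig(
            {"g": fm.ChannelStyle(mode="static", static_color=(255, 255, 255),
                                  opacity=1.0)},
            layer_opacity=0.5,
        )
        tile = fm.composite(base, [(mask, cfg)])
        assert (tile.rgba[..., :3] == 128).all()  # 0.5 * 255 rounded

    def test_invisible_layer_is_skipped(self):
        base = self._base()
        p = np.ones((8, 8), dtype=np.int64)
        mask = fm.MultiChannelBitmask([fm.BitmaskChannel("g", p)])
        cfg = fm.LayerConfig(
            {"g": fm.ChannelStyle(mode="static", static_color=(255, 0, 0))},
            layer_is_visible=False,
        )
        assert np.array_equal(fm.composite(base, [(mask, cfg)]).rgba[..., :3], base)

    def test_shape_mismatch_raises(self):
        mask = fm.MultiChannelBitmask(
            [fm.BitmaskChannel("g", np.zeros((4, 4), dtype=np.int64))]
        )
        with pytest.raises(DimensionError):
            fm.composite(self._base(8), [(mask, fm.LayerConfig())])


class TestRenderRegion:
    @pytest.fixture()
    def styled(self, default_dataset):
        ds, _ = default_dataset
        cfg = fm.LayerConfig(
            {
                "glomerulus": fm.ChannelStyle(
                    mode="static", static_color=(255, 0, 0), opacity=0.7
                ),
                "tubule": fm.ChannelStyle(
                    mode="static", static_color=(0, 80, 255),
                    is_filled=False, stroke_width=2,
                ),
            }
        )
        return ds, cfg

    def test_full_viewport_equals_composite(self, styled):
        ds, cfg = styled
        h, w = ds.image.shape[:2]
        tile = fm.render_region(ds, cfg, (0, 0, h, w))
        full = fm.composite(ds.image, [(ds.bitmask, cfg)])
        assert np.array_equal(tile.rgba, full.rgba)

    def test_viewport_slicing_instance_matches_full_render_crop(self, styled):
        ds, cfg = styled
        h, w = ds.image.shape[:2]
        full = fm.composite(ds.image, [(ds.bitmask, cfg)])
        vp = (h // 4, w // 4, h // 2, w // 2)
        tile = fm.render_region(ds, cfg, vp)
        r0, c0, rows, cols = vp
        assert np.array_equal(tile.rgba, full.rgba[r0 : r0 + rows, c0 : c0 + cols])

    def test_background_viewport_is_pure_image_crop(self, default_dataset):
        ds, _ = default_dataset
        plane_any = np.zeros(ds.image.shape[:2], dtype=bool)
        for ch in ds.bitmask:
            plane_any |= ch.plane > 0
        # find an 8x8 all-background window
        found = None
        for r in range(0, plane_any.shape[0] - 8, 8):
            for c in range(0, plane_any.shape[1] - 8, 8):
                if not plane_any[r : r + 8, c : c + 8].any():
                    found = (r, c)
                    break
            if found:
                break
        assert found is not None
        r, c = found
        cfg = fm.LayerConfig(
            {"ptc": fm.ChannelStyle(mode="static", static_color=(255, 0, 0))}
        )
        tile = fm.render_region(ds, cfg, (r, c, 8, 8))
        assert np.array_equal(tile.rgba[..., :3], ds.image[r : r + 8, c : c + 8])

    def test_out_of_bounds_viewport_raises(self, styled):
        ds, cfg = styled
        h, w = ds.image.shape[:2]
        for vp in [(-1, 0, 8, 8), (0, 0, h + 1, w), (h - 4, w - 4, 8, 8),
                   (0, 0, 0, 4)]:
            with pytest.raises(BoundsError):
                fm.render_region(ds, cfg, vp)

    def test_png_written_matches_tile(self, styled, tmp_path):
        from PIL import Image

        ds, cfg = styled
        p = tmp_path / "tile.png"
        tile = fm.render_region(ds, cfg, (10, 10, 32, 32), out_path=p)
        assert np.array_equal(np.asarray(Image.open(p)), tile.rgba)


def test_load_layer_config_round_trips_field_names(tmp_path):
    cfg_json = {
        "isVisible": True,
        "opacity": 0.8,
        "channels": {
            "glomerulus": {
                "mode": "static", "staticColor": [255, 0, 0],
                "isFilled": False, "strokeWidth": 2, "opacity": 0.9,
                "colormapRangeStart": 0.1, "colormapRangeEnd": 0.9,
            },
            "tubule": {
                "mode": "feature", "featureValues": {"1": 2.0, "2": 5.0},
                "colormapName": "magma",
            },
        },
    }
    p = tmp_path / "cfg.json"
    p.write_text(__import__("json").dumps(cfg_json))
    cfg = fm.load_layer_config(p)
    g = cfg.channel_styles["glomerulus"]
    assert (g.static_color, g.is_filled, g.stroke_width) == ((255, 0, 0), False, 2)
    assert g.colormap_range_start == 0.1 and g.opacity == 0.9
    t = cfg.channel_styles["tubule"]
    assert t.feature_values == {1: 2.0, 2: 5.0} and t.colormap_name == "magma"
    assert cfg.layer_opacity == 0.8


def test_load_layer_config_rejects_invalid_style():
    with pytest.raises(StyleError):
        fm.load_layer_config(
            {"channels": {"g": {"colormapRangeStart": 0.9,
                                "colormapRangeEnd": 0.1}}}
        )
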