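"""CPU re-implementation of the bitmask fragment-shader rendering semantics.

A filled instance bitmask can be rendered either *filled* (every instance
pixel colored) or *stroked* (only pixels near an instance boundary colored),
without precomputing a separate outline image.  The stroked test for a pixel
with value ``v`` samples the plane at offset ``strokeWidth`` in the eight
compass directions; if any of the eight samples differs from ``v`` the pixel
lies within ``strokeWidth`` pixels of a boundary and is rendered.  Background
pixels (value 0) are never rendered, so outlines are drawn on
instance-interior pixels only and an instance's outline never spills outside
its own mask.  Out-of-bounds samples read as background, so instances touching
the image border are outlined there too.

Each channel carries its own visual properties -- visibility, filled/stroked,
stroke width, opacity, colormap window -- and one of three color modes:

``static``
    one RGB color for all non-background pixels of the channel;
``set``
    a categorical mapping instance -> set -> RGB (e.g. sclerotic vs
    non-sclerotic glomeruli); instances without a set render transparent;
``feature``
    a quantitative colormap (viridis or magma) over a per-instance feature
    vector, min-max normalized and windowed by
    ``[colormapRangeStart, colormapRangeEnd]`` with clamping.

Channels are alpha-composited in order over the base image with straight
(non-premultiplied) alpha in floating point, quantized once at the end.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from matplotlib import colormaps as _mpl_colormaps

from .errors import BoundsError, DimensionError, StyleError
from .model import BitmaskChannel, MultiChannelBitmask, SegmentationDataset

__all__ = [
    "ChannelStyle",
    "LayerConfig",
    "RenderedTile",
    "stroked_mask",
    "render_channel",
    "composite",
    "render_region",
    "load_layer_config",
]

COLOR_MODES = ("static", "set", "feature")
COLORMAPS = ("viridis", "magma")

RGB = tuple[int, int, int]


@dataclass
class ChannelStyle:
    """Per-channel visual properties.

    Field names mirror the JSON configuration keys (camelCase in JSON,
    snake_case here): isVisible, isFilled, strokeWidth, opacity, mode,
    staticColor, setColors, instanceSets, featureValues, colormapName,
    colormapRangeStart, colormapRangeEnd.
    """

    is_visible: bool = True
    is_filled: bool = True
    stroke_width: int = 1
    opacity: float = 1.0
    mode: str = "static"
    static_color: RGB = (255, 255, 255)
    set_colors: Optional[dict[int, RGB]] = None      # set ID -> RGB
    instance_sets: Optional[dict[int, int]] = None   # instance ID -> set ID
    feature_values: Optional[dict[int, float]] = None
    colormap_name: str = "viridis"
    colormap_range_start: float = 0.0
    colormap_range_end: float = 1.0

    def validate(self) -> None:
        if self.mode not in COLOR_MODES:
            raise StyleError(f"unknown color mode {self.mode!r}")
        if self.colormap_name not in COLORMAPS:
            raise StyleError(f"unknown colormap {self.colormap_name!r}")
        if not 0.0 <= self.colormap_range_start < self.colormap_range_end <= 1.0:
            raise StyleError(
                "require 0 <= colormapRangeStart < colormapRangeEnd <= 1, got "
                f"[{self.colormap_range_start}, {self.colormap_range_end}]"
            )
        if self.stroke_width < 1:
            raise StyleError(f"strokeWidth must be >= 1, got {self.stroke_width}")
        if not 0.0 <= self.opacity <= 1.0:
            raise StyleError(f"opacity must be in [0, 1], got {self.opacity}")
        if self.mode == "set" and not self.set_colors:
            raise StyleError("set mode requires a non-empty set-color mapping")
        if self.mode == "feature" and not self.feature_values:
            raise StyleError("feature mode requires a non-empty feature-value vector")


@dataclass
class LayerConfig:
    """One segmentation layer: layer-level properties over per-channel styles.

    ``channel_styles`` is an ordered mapping from channel name to
    :class:`ChannelStyle`; channels are composited in this order.
    """

    channel_styles: dict[str, ChannelStyle] = field(default_factory=dict)
    layer_is_visible: bool = True
    layer_opacity: float = 1.0


@dataclass
class RenderedTile:
    """8-bit RGBA raster produced by compositing styled channels over a base."""

    rgba: np.ndarray

    def to_png(self, path: Union[str, os.PathLike]) -> None:
        from PIL import Image

        Image.fromarray(self.rgba, mode="RGBA").save(path, format="PNG")


# ---------------------------------------------------------------------------
# Stroked-mask rule
# ---------------------------------------------------------------------------

_OFFSETS = [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)]


def stroked_mask(
    ch: Union[BitmaskChannel, np.ndarray], stroke_width: int
) -> np.ndarray:
    """Boolean raster of pixels rendered in stroked mode.

    A pixel with instance value ``v > 0`` is stroked iff at least one of the
    eight samples at offset ``stroke_width`` in directions N, S, E, W, NW, NE,
    SW, SE differs from ``v``.  Out-of-bounds samples read as background (0).
    Background pixels are never stroked.
    """
    plane = ch.plane if isinstance(ch, BitmaskChannel) else np.asarray(ch)
    if stroke_width < 1:
        raise StyleError(f"strokeWidth must be >= 1, got {stroke_width}")
    w = int(stroke_width)
    padded = np.pad(plane, w, mode="constant", constant_values=0)
    h, wd = plane.shape
    differs = np.zeros(plane.shape, dtype=bool)
    for dr, dc in _OFFSETS:
        r0, c0 = w + dr * w, w + dc * w
        shifted = padded[r0 : r0 + h, c0 : c0 + wd]
        differs |= shifted != plane
    return (plane > 0) & differs


# ---------------------------------------------------------------------------
# Per-channel rendering
# ---------------------------------------------------------------------------

def _colormap_lut(name: str, t: np.ndarray) -> np.ndarray:
    """Map values in [0, 1] through a matplotlib colormap to 8-bit RGB."""
    rgba = _mpl_colormaps[name](t)
    return np.round(np.asarray(rgba)[..., :3] * 255.0).astype(np.uint8)


def _feature_colors(style: ChannelStyle) -> dict[int, np.ndarray]:
    vals = {int(k): float(v) for k, v in style.feature_values.items()}
    arr = np.array(list(vals.values()), dtype=float)
    vmin, vmax = arr.min(), arr.max()
    if vmin == vmax:
        norm = {i: 0.5 for i in vals}  # constant vector convention
    else:
        norm = {i: (v - vmin) / (vmax - vmin) for i, v in vals.items()}
    lo, hi = style.colormap_range_start, style.colormap_range_end
    t = np.clip(
        (np.array([norm[i] for i in vals]) - lo) / (hi - lo), 0.0, 1.0
    )
    rgb = _colormap_lut(style.colormap_name, t)
    return {i: rgb[k] for k, i in enumerate(vals)}


def render_channel(ch: BitmaskChannel, style: ChannelStyle) -> np.ndarray:
    """Render one channel to an (H, W, 4) uint8 straight-alpha RGBA raster.

    Background is transparent.  Non-background pixels get the mode's color;
    in stroked mode (``is_filled`` False) only pixels passing
    :func:`stroked_mask` are colored.  An invisible channel renders fully
    transparent.  Instances absent from the set map (set mode) or the feature
    vector (feature mode) render transparent.
    """
    style.validate()
    plane = ch.plane
    out = np.zeros(plane.shape + (4,), dtype=np.uint8)
    if not style.is_visible:
        return out

    shown = plane > 0
    if not style.is_filled:
        shown &= stroked_mask(plane, style.stroke_width)
    if not shown.any():
        return out

    alpha = int(round(style.opacity * 255))

    if style.mode == "static":
        out[shown, 0:3] = np.asarray(style.static_color, dtype=np.uint8)
        out[shown, 3] = alpha
        return out

    if style.mode == "set":
        id_to_rgb = {
            int(i): style.set_colors[s]
            for i, s in (style.instance_sets or {}).items()
            if s in style.set_colors
        }
    else:  # feature
        id_to_rgb = _feature_colors(style)

    max_id = int(plane.max())
    lut = np.zeros((max_id + 1, 4), dtype=np.uint8)
    for i, rgb in id_to_rgb.items():
        if i <= max_id:
            lut[i, 0:3] = np.asarray(rgb, dtype=np.uint8)
            lut[i, 3] = alpha
    colored = lut[plane]
    out[shown] = colored[shown]
    return out


# ---------------------------------------------------------------------------
# Compositing
# ---------------------------------------------------------------------------

def _over(dst_rgb: np.ndarray, src_rgba: np.ndarray) -> np.ndarray:
    """Straight-alpha 'over' of an RGBA layer onto an opaque RGB float base."""
    a = src_rgba[..., 3:4]
    return src_rgba[..., :3] * a + dst_rgb * (1.0 - a)


def composite(
    base: np.ndarray,
    layers: Sequence[tuple[MultiChannelBitmask, LayerConfig]],
) -> RenderedTile:
    """Composite styled segmentation layers over a base RGB image.

    Channels are composited in listed order (within each layer, in the order
    of ``channel_styles``); ``layer_opacity`` multiplies each channel's alpha.
    The result is fully opaque.
    """
    base = np.asarray(base)
    if base.ndim != 3 or base.shape[2] < 3:
        raise DimensionError(f"base image must be (H, W, 3+), got {base.shape}")
    acc = base[..., :3].astype(np.float64) / 255.0
    for mask, config in layers:
        if mask.shape != base.shape[:2]:
            raise DimensionError(
                f"bitmask shape {mask.shape} != image shape {base.shape[:2]}"
            )
        if not config.layer_is_visible:
            continue
        for name, style in config.channel_styles.items():
            ch = mask[name]
            rgba = render_channel(ch, style).astype(np.float64) / 255.0
            rgba[..., 3] *= config.layer_opacity
            acc = _over(acc, rgba)
    h, w = base.shape[:2]
    out = np.empty((h, w, 4), dtype=np.uint8)
    out[..., :3] = np.round(np.clip(acc, 0.0, 1.0) * 255.0).astype(np.uint8)
    out[..., 3] = 255
    return RenderedTile(out)


def render_region(
    ds: SegmentationDataset,
    config: LayerConfig,
    viewport: tuple[int, int, int, int],
    out_path: Optional[Union[str, os.PathLike]] = None,
) -> RenderedTile:
    """Render a rectangular viewport ``(row0, col0, rows, cols)`` to RGBA/PNG.

    Stroked masks are computed on the full plane *before* cropping, so
    outlines of instances sliced by the viewport edge are identical to the
    corresponding region of a full-frame render.
    """
    if ds.image is None:
        raise DimensionError("dataset has no base image to render over")
    r0, c0, rows, cols = viewport
    H, W = ds.image.shape[:2]
    if r0 < 0 or c0 < 0 or rows < 1 or cols < 1 or r0 + rows > H or c0 + cols > W:
        raise BoundsError(
            f"viewport {viewport} outside image bounds ({H}, {W})"
        )
    base = ds.image[r0 : r0 + rows, c0 : c0 + cols, :3].astype(np.float64) / 255.0
    acc = base
    if config.layer_is_visible:
        for name, style in config.channel_styles.items():
            ch = ds.bitmask[name]
            rgba = render_channel(ch, style).astype(np.float64) / 255.0
            rgba = rgba[r0 : r0 + rows, c0 : c0 + cols]
            rgba[..., 3] *= config.layer_opacity
            acc = _over(acc, rgba)
    out = np.empty((rows, cols, 4), dtype=np.uint8)
    out[..., :3] = np.round(np.clip(acc, 0.0, 1.0) * 255.0).astype(np.uint8)
    out[..., 3] = 255
    tile = RenderedTile(out)
    if out_path is not None:
        tile.to_png(out_path)
    return tile


# ---------------------------------------------------------------------------
# JSON configuration
# ---------------------------------------------------------------------------

_STYLE_KEYS = {
    "isVisible": "is_visible",
    "isFilled": "is_filled",
    "strokeWidth": "stroke_width",
    "opacity": "opacity",
    "mode": "mode",
    "staticColor": "static_color",
    "colormapName": "colormap_name",
    "colormapRangeStart": "colormap_range_start",
    "colormapRangeEnd": "colormap_range_end",
}


def _style_from_dict(d: dict) -> ChannelStyle:
    kwargs: dict = {}
    for json_key, attr in _STYLE_KEYS.items():
        if json_key in d:
            v = d[json_key]
            kwargs[attr] = tuple(v) if json_key == "staticColor" else v
    if "setColors" in d:
        kwargs["set_colors"] = {int(k): tuple(v) for k, v in d["setColors"].items()}
    if "instanceSets" in d:
        kwargs["instance_sets"] = {int(k): int(v) for k, v in d["instanceSets"].items()}
    if "featureValues" in d:
        kwargs["feature_values"] = {
            int(k): float(v) for k, v in d["featureValues"].items()
        }
    style = ChannelStyle(**kwargs)
    style.validate()
    return style


def load_layer_config(source: Union[str, os.PathLike, dict]) -> LayerConfig:
    """Build a :class:`LayerConfig` from a JSON file or already-parsed dict.

    Schema::

        {"isVisible": true, "opacity": 1.0,
         "channels": {"glomerulus": {"mode": "static", "staticColor": [255,0,0],
                                     "isFilled": false, "strokeWidth": 2, ...}}}
    """
    if isinstance(source, dict):
        d = source
    else:
        d = json.loads(Path(source).read_text())
    styles = {
        name: _style_from_dict(sd) for name, sd in d.get("channels", {}).items()
    }
    return LayerConfig(
        channel_styles=styles,
        layer_is_visible=d.get("isVisible", True),
        layer_opacity=d.get("opacity", 1.0),
    )
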