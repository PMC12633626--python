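"""Synthetic kidney-like fixture generator.

Builds fully conformant datasets -- a pale PAS-pink tissue background with
elliptical/disk/blob functional-tissue-unit instances of several observation
types, optional annotated region channels (IFTA-like blobs), ground-truth
feature tables and per-instance generation records -- so every other module
is testable without any external download.

Determinism: one global seed drives a :class:`numpy.random.SeedSequence`
that is split into one child stream per channel (image noise first, then
region channels, then instance channels, in spec order), so adding an
instance type never changes the pixels of earlier channels.

Realism is intentionally limited: instance colors are constants per type
(color-feature recovery is exact), the background carries only low-amplitude
Gaussian noise, and instances never overlap within a channel.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import PlacementError
from .model import (
    BitmaskChannel,
    FeatureTable,
    MultiChannelBitmask,
    SegmentationDataset,
)

__all__ = [
    "TypeSpec",
    "RegionSpec",
    "SynthSpec",
    "GroundTruth",
    "InstanceRecord",
    "generate_dataset",
    "default_spec",
    "stratified_spec",
]

BACKGROUND_RGB = (243, 217, 227)  # pale PAS-like pink
NOISE_SD = 4.0
MAX_TRIES = 200  # rejection-sampling retry budget per instance


@dataclass
class TypeSpec:
    """One instance channel: what to place and how it looks.

    ``size_range`` is the sampling interval for the shape's size parameter in
    pixels: disk radius, ellipse semi-major axis (the semi-minor axis is
    drawn between half the size and the size), or blob lobe radius.  When
    ``effect_region`` names a region channel, instances whose center falls on
    that region use ``inside_size_range`` instead -- the hook for simulating
    region-dependent morphology (e.g. smaller capillaries inside IFTA).
    """

    name: str
    n_instances: int
    shape_kind: str = "disk"  # disk | ellipse | blob
    size_range: tuple[float, float] = (4.0, 8.0)
    color: tuple[int, int, int] = (180, 80, 110)
    effect_region: Optional[str] = None
    inside_size_range: Optional[tuple[float, float]] = None


@dataclass
class RegionSpec:
    """One annotated region channel made of large overlapping blobs."""

    name: str
    n_blobs: int = 2
    coverage_fraction: float = 0.2


@dataclass
class SynthSpec:
    shape: tuple[int, int] = (256, 256)
    types: list[TypeSpec] = field(default_factory=list)
    region_types: list[RegionSpec] = field(default_factory=list)
    seed: int = 0
    pixel_size: Optional[float] = 0.5  # µm per pixel
    gapped_ids: bool = False  # remap IDs through a random gapped injection

    @classmethod
    def from_json(cls, path: Union[str, os.PathLike]) -> "SynthSpec":
        d = json.loads(Path(path).read_text())
        types = [TypeSpec(**{**t, "size_range": tuple(t["size_range"]),
                             "color": tuple(t.get("color", (180, 80, 110)))})
                 for t in d.pop("types", [])]
        regions = [RegionSpec(**r) for r in d.pop("region_types", [])]
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        return cls(types=types, region_types=regions, **d)


@dataclass
class InstanceRecord:
    """Ground truth for one placed instance."""

    observation_type: str
    id: int
    shape_kind: str
    area_px: int
    centroid_row: float
    centroid_col: float
    axis_a: float  # disk radius or ellipse semi-major axis
    axis_b: float  # disk radius or ellipse semi-minor axis
    theta: float   # ellipse orientation, radians
    region_labels: dict[str, str] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Per-instance generation records, keyed by observation type."""

    instances: dict[str, list[InstanceRecord]] = field(default_factory=dict)

    def records(self, observation_type: str) -> list[InstanceRecord]:
        return self.instances.get(observation_type, [])

    def to_json(self, path: Union[str, os.PathLike]) -> None:
        d = {
            t: [asdict(r) for r in recs] for t, recs in self.instances.items()
        }
        Path(path).write_text(json.dumps(d, indent=2))


def default_spec(seed: int = 0) -> SynthSpec:
    """The standard fixture: three FTU channels on a 256x256 canvas.

    A handful of large glomerulus disks, mid-sized tubule ellipses, and many
    small peritubular-capillary disks -- roughly the relative abundances and
    size ordering seen in cortical kidney tissue at low magnification.
    """
    return SynthSpec(
        shape=(256, 256),
        types=[
            TypeSpec("glomerulus", 4, "disk", (10.0, 16.0), (150, 60, 95)),
            TypeSpec("tubule", 8, "ellipse", (8.0, 14.0), (214, 145, 168)),
            TypeSpec("ptc", 20, "disk", (2.0, 4.0), (120, 40, 60)),
        ],
        seed=seed,
    )


def stratified_spec(seed: int = 0, n_ptc: int = 40) -> SynthSpec:
    """Fixture for the region-stratification case study.

    One IFTA-like region channel covering ~25% of the canvas, plus
    peritubular capillaries whose radii are drawn smaller inside the region
    (2.0-3.5 px) than outside (4.0-6.0 px) -- a known size shift whose sign
    the stratified comparison should recover.
    """
    return SynthSpec(
        shape=(256, 256),
        types=[
            TypeSpec(
                "ptc", n_ptc, "disk", (4.0, 6.0), (120, 40, 60),
                effect_region="ifta", inside_size_range=(2.0, 3.5),
            ),
        ],
        region_types=[RegionSpec("ifta", n_blobs=2, coverage_fraction=0.25)],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Shape stamps
# ---------------------------------------------------------------------------

def _disk_stamp(r: float) -> np.ndarray:
    n = int(np.ceil(r))
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    return (yy**2 + xx**2) <= r**2


def _ellipse_stamp(a: float, b: float, theta: float) -> np.ndarray:
    n = int(np.ceil(max(a, b)))
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    ct, st = np.cos(theta), np.sin(theta)
    u = xx * ct + yy * st
    v = -xx * st + yy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _blob_stamp(r: float, rng: np.random.Generator) -> np.ndarray:
    """Union of 3-5 jittered disks: an irregular but compact region."""
    k = int(rng.integers(3, 6))
    n = int(np.ceil(2.2 * r))
    canvas = np.zeros((2 * n + 1, 2 * n + 1), dtype=bool)
    for _ in range(k):
        rr = r * rng.uniform(0.6, 1.0)
        dy, dx = rng.uniform(-0.8 * r, 0.8 * r, size=2)
        yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
        canvas |= (yy - dy) ** 2 + (xx - dx) ** 2 <= rr**2
    return canvas


def _place_stamp(
    plane: np.ndarray, stamp: np.ndarray, rng: np.random.Generator,
    avoid_overlap: bool,
) -> Optional[tuple[int, int]]:
    """Try to place a stamp at a random location; returns top-left or None."""
    H, W = plane.shape
    sh, sw = stamp.shape
    if sh > H or sw > W:
        return None
    for _ in range(MAX_TRIES):
        r0 = int(rng.integers(0, H - sh + 1))
        c0 = int(rng.integers(0, W - sw + 1))
        window = plane[r0 : r0 + sh, c0 : c0 + sw]
        if avoid_overlap and (window[stamp] != 0).any():
            continue
        return r0, c0
    return None


def _gapped_id_map(n: int, rng: np.random.Generator) -> list[int]:
    """Order-preserving injection 1..n -> positive ints with random gaps."""
    ids, cur = [], 0
    for _ in range(n):
        cur += 1 + int(rng.integers(0, 3))
        ids.append(cur)
    return ids


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_dataset(spec: SynthSpec) -> tuple[SegmentationDataset, GroundTruth]:
    """Generate a conformant dataset plus its ground truth.

    Instances never overlap within a channel (rejection sampling with a retry
    budget; :class:`PlacementError` when the canvas cannot fit the request).
    Region blobs may overlap each other.  The ground-truth area of each
    instance is recounted from the painted plane, so it is exact by
    construction.
    """
    H, W = spec.shape
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(1 + len(spec.region_types) + len(spec.types))
    img_rng = np.random.default_rng(children[0])

    image = np.clip(
        np.array(BACKGROUND_RGB, dtype=np.float64)
        + img_rng.normal(0.0, NOISE_SD, size=(H, W, 3)),
        0, 255,
    ).astype(np.uint8)

    gt = GroundTruth()
    channels: list[BitmaskChannel] = []
    tables: dict[str, FeatureTable] = {}

    region_planes: dict[str, np.ndarray] = {}
    for k, rspec in enumerate(spec.region_types):
        rng = np.random.default_rng(children[1 + k])
        plane = np.zeros((H, W), dtype=np.uint32)
        if rspec.n_blobs > 0 and rspec.coverage_fraction > 0:
            target = rspec.coverage_fraction * H * W
            r = np.sqrt(target / (rspec.n_blobs * np.pi))
            for bid in range(1, rspec.n_blobs + 1):
                stamp = _blob_stamp(r, rng)
                pos = _place_stamp(plane, stamp, rng, avoid_overlap=False)
                if pos is None:
                    raise PlacementError(
                        f"cannot place region blob {bid} of {rspec.name!r}"
                    )
                r0, c0 = pos
                plane[r0 : r0 + stamp.shape[0], c0 : c0 + stamp.shape[1]][stamp] = bid
        region_planes[rspec.name] = plane
        channels.append(BitmaskChannel(rspec.name, plane, pixel_size=spec.pixel_size))

    base = 1 + len(spec.region_types)
    for k, tspec in enumerate(spec.types):
        rng = np.random.default_rng(children[base + k])
        plane = np.zeros((H, W), dtype=np.uint32)
        ids = (
            _gapped_id_map(tspec.n_instances, rng)
            if spec.gapped_ids
            else list(range(1, tspec.n_instances + 1))
        )
        records: list[InstanceRecord] = []
        for inst_id in ids:
            placed = False
            for _ in range(MAX_TRIES):
                # sample a tentative center first so region-dependent sizing
                # is decided before the stamp is built
                r_c = int(rng.integers(0, H))
                c_c = int(rng.integers(0, W))
                size_range = tspec.size_range
                region_label = None
                if tspec.effect_region is not None:
                    inside = bool(region_planes[tspec.effect_region][r_c, c_c] > 0)
                    region_label = "inside" if inside else "outside"
                    if inside and tspec.inside_size_range is not None:
                        size_range = tspec.inside_size_range
                size = float(rng.uniform(*size_range))
                theta = 0.0
                if tspec.shape_kind == "disk":
                    stamp, a, b = _disk_stamp(size), size, size
                elif tspec.shape_kind == "ellipse":
                    b = float(rng.uniform(size / 2.0, size))
                    theta = float(rng.uniform(0.0, np.pi))
                    stamp, a = _ellipse_stamp(size, b, theta), size
                elif tspec.shape_kind == "blob":
                    stamp, a, b = _blob_stamp(size, rng), size, size
                else:
                    raise ValueError(f"unknown shape_kind {tspec.shape_kind!r}")
                sh, sw = stamp.shape
                r0, c0 = r_c - sh // 2, c_c - sw // 2
                if r0 < 0 or c0 < 0 or r0 + sh > H or c0 + sw > W:
                    continue
                window = plane[r0 : r0 + sh, c0 : c0 + sw]
                if (window[stamp] != 0).any():
                    continue
                window[stamp] = inst_id
                image[r0 : r0 + sh, c0 : c0 + sw][stamp] = tspec.color
                rr, cc = np.nonzero(plane == inst_id)
                rec = InstanceRecord(
                    observation_type=tspec.name,
                    id=inst_id,
                    shape_kind=tspec.shape_kind,
                    area_px=int(len(rr)),
                    centroid_row=float(rr.mean()),
                    centroid_col=float(cc.mean()),
                    axis_a=a,
                    axis_b=b,
                    theta=theta,
                )
                if region_label is not None:
                    rec.region_labels[tspec.effect_region] = region_label
                records.append(rec)
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"cannot place instance {inst_id} of {tspec.name!r} "
                    f"within {MAX_TRIES} tries"
                )
        gt.instances[tspec.name] = records
        channels.append(BitmaskChannel(tspec.name, plane, pixel_size=spec.pixel_size))
        tables[tspec.name] = _ground_truth_table(tspec.name, records)

    ds = SegmentationDataset(
        bitmask=MultiChannelBitmask(channels), image=image, tables=tables
    )
    return ds, gt


def _ground_truth_table(name: str, records: list[InstanceRecord]) -> FeatureTable:
    import pandas as pd

    ids = [r.id for r in records]
    cols: dict[str, object] = {
        "area_px": [float(r.area_px) for r in records],
        "centroid_row": [r.centroid_row for r in records],
        "centroid_col": [r.centroid_col for r in records],
        "shape_kind": pd.Categorical([r.shape_kind for r in records]),
    }
    if records and records[0].region_labels:
        region = next(iter(records[0].region_labels))
        cols[f"in_{region}"] = pd.Categorical(
            [r.region_labels.get(region, "outside") for r in records]
        )
    return FeatureTable.from_columns(name, ids, cols)
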