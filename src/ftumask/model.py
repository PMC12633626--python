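"""Core domain types for multi-observation-type segmentation bitmasks.

The convention represented here is the one used to publish whole-slide
segmentation results for kidney biopsies: a multi-channel integer label image
in which each channel holds one *observation type* (glomerulus, tubule,
peritubular capillary, ...), pixel value 0 means background and pixel value
``i > 0`` marks the i-th instance of that type.  Each channel may be linked to
an observation-by-feature table whose row index holds the instance IDs --
1-indexed positive integers that need not be sequential or gapless.

Everything in this module is an in-memory value object; serialization lives in
:mod:`ftumask.io_formats`.  Constructors are deliberately permissive: invalid
datasets can be built and then inspected with :func:`validate_dataset`, which
reports violations as *data* rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import UnknownFeatureError, UnknownTypeError

__all__ = [
    "BitmaskChannel",
    "MultiChannelBitmask",
    "FeatureTable",
    "TableManifest",
    "SegmentationDataset",
    "Violation",
    "ValidationReport",
    "validate_dataset",
    "instances_in_channel",
    "join_features",
]


@dataclass
class BitmaskChannel:
    """One observation type's instance label plane.

    Parameters
    ----------
    name:
        Observation-type label, e.g. ``"glomerulus"``.
    plane:
        2-D integer raster, rows x cols.  0 is background; a positive value
        ``i`` marks every pixel of instance ``i``.
    pixel_size:
        Optional physical size of one (isotropic) pixel in micrometres.
    """

    name: str
    plane: np.ndarray
    pixel_size: Optional[float] = None

    def __post_init__(self) -> None:
        self.plane = np.asarray(self.plane)

    @property
    def shape(self) -> tuple[int, int]:
        return self.plane.shape  # type: ignore[return-value]


@dataclass
class MultiChannelBitmask:
    """Ordered collection of :class:`BitmaskChannel` sharing one raster grid."""

    channels: list[BitmaskChannel]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    def __getitem__(self, name: str) -> BitmaskChannel:
        for c in self.channels:
            if c.name == name:
                return c
        raise UnknownTypeError(f"no channel named {name!r}")

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __iter__(self):
        return iter(self.channels)

    def stack(self) -> np.ndarray:
        """Return the channels as a single (C, rows, cols) array."""
        return np.stack([c.plane for c in self.channels])


class FeatureTable:
    """Observation-by-feature matrix for one observation type.

    Thin wrapper around a :class:`pandas.DataFrame` whose integer index holds
    the instance IDs.  IDs are 1-indexed positive integers and join by *value*
    against the pixel values of the matching bitmask channel -- never by row
    position, because IDs are allowed to be non-sequential and gapped.
    Columns may be numeric (float) or categorical text.
    """

    def __init__(self, observation_type: str, data: pd.DataFrame):
        self.observation_type = observation_type
        data = data.copy()
        data.index = pd.Index(np.asarray(data.index), name="id")
        self.data = data

    @classmethod
    def from_columns(
        cls,
        observation_type: str,
        ids: Sequence[int],
        columns: Mapping[str, Sequence],
    ) -> "FeatureTable":
        df = pd.DataFrame(dict(columns), index=np.asarray(ids, dtype=np.int64))
        return cls(observation_type, df)

    @property
    def ids(self) -> np.ndarray:
        return np.asarray(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"FeatureTable({self.observation_type!r}, n={len(self)}, "
            f"columns={self.columns})"
        )

    def equals(self, other: "FeatureTable") -> bool:
        """Value equality: same type, ids, column names/order and cell values."""
        if self.observation_type != other.observation_type:
            return False
        if self.columns != other.columns:
            return False
        if not np.array_equal(self.ids, other.ids):
            return False
        for col in self.columns:
            a, b = self.data[col], other.data[col]
            a_num = pd.api.types.is_numeric_dtype(a)
            if a_num != pd.api.types.is_numeric_dtype(b):
                return False
            if a_num:
                if not np.allclose(
                    a.to_numpy(dtype=float), b.to_numpy(dtype=float), equal_nan=True
                ):
                    return False
            else:
                if list(map(str, a)) != list(map(str, b)):
                    return False
        return True


@dataclass
class TableManifest:
    """Linking structure between single-table files and bitmask channels.

    A list of ``(table_uri, observation_type)`` pairs; at most one entry per
    observation type.  Needed because single-table formats (CSV, standalone
    AnnData) carry no channel linkage of their own.
    """

    entries: list[tuple[str, str]] = field(default_factory=list)

    def observation_types(self) -> list[str]:
        return [t for _, t in self.entries]


@dataclass
class SegmentationDataset:
    """The bound triple: base image, multi-channel bitmask, linked tables."""

    bitmask: MultiChannelBitmask
    image: Optional[np.ndarray] = None
    tables: dict[str, FeatureTable] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class Violation:
    code: str
    message: str
    location: str

    def to_dict(self) -> dict:
        return {"code": self.code, "message": self.message, "location": self.location}


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    @property
    def codes(self) -> list[str]:
        return [v.code for v in self.violations]

    def __len__(self) -> int:
        return len(self.violations)

    def __iter__(self):
        return iter(self.violations)

    def to_dict(self) -> dict:
        return {"ok": self.ok, "violations": [v.to_dict() for v in self.violations]}


def validate_dataset(ds: SegmentationDataset, strict: bool = False) -> ValidationReport:
    """Check a dataset against every invariant of the representation.

    All violations found are returned, not just the first; an empty report is
    equivalent to full conformance.  In ``strict`` mode a table row whose ID
    has no pixel in the channel is flagged as ``ORPHAN_ID``; by default orphan
    rows are tolerated because cropping an image can legitimately remove
    instances whose feature rows survive.
    """
    out: list[Violation] = []

    def add(code: str, message: str, location: str) -> None:
        out.append(Violation(code, message, location))

    channels = ds.bitmask.channels if ds.bitmask is not None else []
    if not channels:
        add("NO_CHANNELS", "bitmask has no channels", "bitmask")
        return ValidationReport(out)

    seen: dict[str, int] = {}
    for i, ch in enumerate(channels):
        loc = f"channel[{i}]({ch.name!r})"
        if not ch.name:
            add("EMPTY_NAME", "channel name is empty", loc)
        if ch.name in seen:
            add(
                "DUPLICATE_CHANNEL_NAME",
                f"channel name {ch.name!r} already used by channel[{seen[ch.name]}]",
                loc,
            )
        else:
            seen[ch.name] = i
        if ch.plane.ndim != 2:
            add("SHAPE_MISMATCH", f"plane is {ch.plane.ndim}-D, expected 2-D", loc)
            continue
        if not np.issubdtype(ch.plane.dtype, np.integer):
            add(
                "NONINTEGER_PIXEL",
                f"plane dtype {ch.plane.dtype} is not an integer type",
                loc,
            )
        elif ch.plane.size and int(ch.plane.min()) < 0:
            add(
                "NEGATIVE_PIXEL",
                f"plane contains negative value {int(ch.plane.min())}",
                loc,
            )
        if ch.plane.shape != channels[0].plane.shape:
            add(
                "SHAPE_MISMATCH",
                f"plane shape {ch.plane.shape} differs from "
                f"channel[0] shape {channels[0].plane.shape}",
                loc,
            )

    if ds.image is not None and ds.image.shape[:2] != channels[0].plane.shape:
        add(
            "IMAGE_SHAPE_MISMATCH",
            f"image spatial shape {ds.image.shape[:2]} differs from bitmask "
            f"shape {channels[0].plane.shape}",
            "image",
        )

    names = set(ds.bitmask.names)
    for obs_type, table in ds.tables.items():
        loc = f"table({obs_type!r})"
        if table.observation_type != obs_type:
            add(
                "UNKNOWN_OBSERVATION_TYPE",
                f"table registered under {obs_type!r} declares type "
                f"{table.observation_type!r}",
                loc,
            )
        if obs_type not in names:
            add(
                "UNKNOWN_OBSERVATION_TYPE",
                f"no bitmask channel named {obs_type!r}",
                loc,
            )
            continue
        ids = table.ids
        if len(np.unique(ids)) != len(ids):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            add("DUPLICATE_ID", f"duplicate instance IDs {dupes}", loc)
        if len(ids) and ids.min() < 1:
            add(
                "NONPOSITIVE_ID",
                f"IDs must be 1-indexed positive integers, found {int(ids.min())}",
                loc,
            )
        cols = pd.Index(table.columns)
        if cols.has_duplicates:
            add(
                "DUPLICATE_COLUMN",
                f"duplicate column names {cols[cols.duplicated()].unique().tolist()}",
                loc,
            )
        ch = ds.bitmask[obs_type]
        if ch.plane.ndim != 2 or not np.issubdtype(ch.plane.dtype, np.integer):
            continue  # pixel/row cross-checks meaningless on a malformed plane
        present = instances_in_channel(ch)
        id_set = set(int(i) for i in ids)
        for v in present:
            if int(v) not in id_set:
                add(
                    "MISSING_TABLE_ROW",
                    f"pixel value {int(v)} present in channel but absent from table",
                    loc,
                )
        if strict:
            present_set = set(int(v) for v in present)
            for i in ids:
                if int(i) not in present_set:
                    add(
                        "ORPHAN_ID",
                        f"table ID {int(i)} has no pixels in channel",
                        loc,
                    )

    return ValidationReport(out)


def instances_in_channel(ch: BitmaskChannel) -> np.ndarray:
    """Distinct positive pixel values of a channel, ascending."""
    vals = np.unique(ch.plane)
    return vals[vals > 0]


def join_features(
    ds: SegmentationDataset, observation_type: str, feature: str
) -> dict[int, object]:
    """Map instance ID -> feature value for one observation type.

    The join is by ID value, never by row position; row order in the table is
    irrelevant.
    """
    if observation_type not in ds.tables:
        raise UnknownTypeError(f"no feature table for {observation_type!r}")
    table = ds.tables[observation_type]
    if feature not in table.columns:
        raise UnknownFeatureError(
            f"table {observation_type!r} has no column {feature!r}"
        )
    col = table.data[feature]
    return {int(i): col.loc[i] for i in table.ids}
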