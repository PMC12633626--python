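"""Serialization of the segmentation convention.

Three on-disk forms are supported:

* a single-file tiled **OME-TIFF** whose planes are the bitmask channels and
  whose embedded OME-XML carries the channel names (one channel = one
  observation type);
* an **NGFF-style chunked directory store** (zarr) holding the base image,
  the label stack and one feature table per observation type, with channel
  names under a ``channel_names`` metadata key;
* **CSV feature tables** linked to channels through a small JSON manifest,
  needed because a CSV carries no channel linkage of its own.

The manifest is a JSON list of ``{"table": <uri>, "observation_type": <name>}``
objects; relative table URIs are resolved against the manifest's directory.
"""

from __future__ import annotations

import json
import os
import warnings
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile
import zarr

from .errors import DimensionError, FormatError, ManifestError, ParseError, WriteError
from .model import (
    BitmaskChannel,
    FeatureTable,
    MultiChannelBitmask,
    SegmentationDataset,
)

__all__ = [
    "write_bitmask_tiff",
    "read_bitmask_tiff",
    "write_store",
    "read_store",
    "read_tables_csv",
    "write_tables_csv",
    "smallest_uint_dtype",
]

PathLike = Union[str, os.PathLike]

_STORE_FORMAT = "ftumask-store"


def smallest_uint_dtype(max_value: int) -> np.dtype:
    """Smallest unsigned integer dtype that can hold ``max_value``."""
    for dt in (np.uint8, np.uint16, np.uint32):
        if max_value <= np.iinfo(dt).max:
            return np.dtype(dt)
    return np.dtype(np.uint64)


# ---------------------------------------------------------------------------
# OME-TIFF
# ---------------------------------------------------------------------------

def write_bitmask_tiff(mask: MultiChannelBitmask, path: PathLike) -> None:
    """Write a multi-channel bitmask as an OME-TIFF, one plane per channel.

    Channel names go into the OME-XML ``Channel/@Name`` fields so any
    conformant reader can recover the observation types.  The sample format is
    the smallest unsigned integer type holding the largest instance ID.
    """
    stack = mask.stack()
    max_id = int(stack.max()) if stack.size else 0
    stack = stack.astype(smallest_uint_dtype(max_id))
    metadata: dict = {
        "axes": "CYX",
        "Channel": {"Name": list(mask.names)},
    }
    ps = mask.channels[0].pixel_size
    if ps is not None:
        metadata.update(
            PhysicalSizeX=ps, PhysicalSizeXUnit="µm",
            PhysicalSizeY=ps, PhysicalSizeYUnit="µm",
        )
    try:
        tifffile.imwrite(
            path, stack, ome=True, photometric="minisblack", metadata=metadata
        )
    except OSError as e:
        raise WriteError(f"cannot write TIFF to {path}: {e}") from e


def _ome_channel_names(ome_xml: str) -> list[str]:
    root = ET.fromstring(ome_xml)
    ns = root.tag.split("}")[0][1:] if root.tag.startswith("{") else ""
    tag = f"{{{ns}}}Channel" if ns else "Channel"
    return [c.get("Name") or "" for c in root.iter(tag)]


def _ome_pixel_size(ome_xml: str) -> Optional[float]:
    root = ET.fromstring(ome_xml)
    ns = root.tag.split("}")[0][1:] if root.tag.startswith("{") else ""
    tag = f"{{{ns}}}Pixels" if ns else "Pixels"
    for p in root.iter(tag):
        v = p.get("PhysicalSizeX")
        if v is not None:
            return float(v)
    return None


def read_bitmask_tiff(path: PathLike) -> MultiChannelBitmask:
    """Read a multi-channel bitmask from an OME-TIFF (or plain TIFF).

    Channel names come from the OME-XML metadata; a plain TIFF without names
    gets synthetic names ``channel_0, channel_1, ...`` and a warning.
    """
    # tifffile salvages what it can from corrupt files, reporting damage
    # through its logger rather than raising; promote that to FORMAT_ERROR
    import logging

    class _Collect(logging.Handler):
        def __init__(self) -> None:
            super().__init__(level=logging.ERROR)
            self.records: list[str] = []

        def emit(self, record: logging.LogRecord) -> None:
            self.records.append(record.getMessage())

    collector = _Collect()
    tiff_logger = logging.getLogger("tifffile")
    tiff_logger.addHandler(collector)
    try:
        try:
            tf = tifffile.TiffFile(path)
        except (tifffile.TiffFileError, ValueError, OSError) as e:
            raise FormatError(f"not a readable TIFF: {path}: {e}") from e
        with tf:
            try:
                arr = tf.series[0].asarray()
            except Exception as e:  # truncated/corrupt data segment
                raise FormatError(f"cannot decode TIFF data in {path}: {e}") from e
            names: list[str] = []
            pixel_size = None
            if tf.ome_metadata:
                try:
                    names = _ome_channel_names(tf.ome_metadata)
                    pixel_size = _ome_pixel_size(tf.ome_metadata)
                except ET.ParseError:
                    names = []
    finally:
        tiff_logger.removeHandler(collector)
    if collector.records:
        raise FormatError(
            f"corrupt or truncated TIFF {path}: {collector.records[0]}"
        )
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise DimensionError(
            f"expected (channels, rows, cols) planes, got shape {arr.shape}"
        )
    n = arr.shape[0]
    if len(names) != n or any(not nm for nm in names):
        names = [f"channel_{i}" for i in range(n)]
        warnings.warn(
            f"{path}: no channel-name metadata; assigning synthetic names {names}",
            stacklevel=2,
        )
    return MultiChannelBitmask(
        [BitmaskChannel(nm, arr[i], pixel_size=pixel_size) for i, nm in enumerate(names)]
    )


# ---------------------------------------------------------------------------
# Chunked directory store (NGFF-style zarr layout)
# ---------------------------------------------------------------------------
#
# Layout:
#   <path>/              zarr group, attrs: format marker
#     image/0            (3, H, W) or (C, H, W) uint8 array  [optional]
#     labels/0           (C, H, W) unsigned-int label stack
#     labels attrs:      channel_names, pixel_size_um, multiscales
#     tables/<type>/     AnnData zarr group per observation type
#
# Multiscale pyramids: only the first (highest-resolution) dataset listed in
# the multiscales metadata is read; pyramid generation is out of scope.

def write_store(ds: SegmentationDataset, path: PathLike) -> None:
    """Write a full dataset as an NGFF-style chunked directory store."""
    path = Path(path)
    root = zarr.open_group(str(path), mode="w")
    root.attrs["format"] = _STORE_FORMAT

    stack = ds.bitmask.stack()
    max_id = int(stack.max()) if stack.size else 0
    stack = stack.astype(smallest_uint_dtype(max_id))
    labels = root.create_group("labels")
    labels.attrs.update(
        {
            "channel_names": list(ds.bitmask.names),
            "multiscales": [{"datasets": [{"path": "0"}]}],
            "pixel_size_um": ds.bitmask.channels[0].pixel_size,
        }
    )
    arr = labels.create_array(
        "0", shape=stack.shape, dtype=stack.dtype,
        chunks=(1, min(256, stack.shape[1]), min(256, stack.shape[2])),
    )
    arr[:] = stack

    if ds.image is not None:
        img = np.asarray(ds.image)
        grp = root.create_group("image")
        grp.attrs["multiscales"] = [{"datasets": [{"path": "0"}]}]
        a = grp.create_array(
            "0", shape=img.shape, dtype=img.dtype,
            chunks=(min(256, img.shape[0]), min(256, img.shape[1])) + img.shape[2:],
        )
        a[:] = img

    if ds.tables:
        (path / "tables").mkdir(exist_ok=True)
        for obs_type, table in ds.tables.items():
            _write_table_anndata(table, path / "tables" / obs_type)


def _write_table_anndata(table: FeatureTable, path: Path) -> None:
    import anndata as ad

    df = table.data
    numeric = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    categorical = [c for c in df.columns if c not in numeric]
    obs = pd.DataFrame(index=df.index.astype(str))
    for c in categorical:
        obs[c] = pd.Categorical(df[c].astype(str))
    X = df[numeric].to_numpy(dtype=np.float64) if numeric else np.zeros((len(df), 0))
    adata = ad.AnnData(X=X, obs=obs)
    adata.var_names = numeric
    adata.uns["observation_type"] = table.observation_type
    adata.uns["column_order"] = list(df.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # anndata zarr-v2 default notice
        adata.write_zarr(str(path))


def _read_table_anndata(path: Path) -> FeatureTable:
    import anndata as ad

    adata = ad.read_zarr(str(path))
    ids = np.asarray([int(i) for i in adata.obs_names], dtype=np.int64)
    cols: dict[str, object] = {}
    Xarr = np.asarray(adata.X) if adata.n_vars else np.zeros((adata.n_obs, 0))
    for j, name in enumerate(adata.var_names):
        cols[name] = Xarr[:, j]
    for name in adata.obs.columns:
        cols[name] = pd.Categorical(adata.obs[name].astype(str))
    order = list(adata.uns.get("column_order", list(cols)))
    df = pd.DataFrame({c: cols[c] for c in order}, index=ids)
    return FeatureTable(str(adata.uns["observation_type"]), df)


def _first_scale_path(attrs: dict, default: str = "0") -> str:
    ms = attrs.get("multiscales")
    if ms:
        datasets = ms[0].get("datasets", [])
        if datasets:
            return datasets[0]["path"]
    return default


def read_store(path: PathLike, strict: bool = True) -> SegmentationDataset:
    """Read a dataset back from a chunked directory store.

    Only the highest-resolution level of any multiscale pyramid is read.  In
    ``strict`` mode a labels group without ``channel_names`` metadata is a
    :class:`FormatError`; otherwise synthetic names are assigned.
    """
    path = Path(path)
    if not path.is_dir():
        raise FormatError(f"not a store directory: {path}")
    try:
        root = zarr.open_group(str(path), mode="r")
    except Exception as e:
        raise FormatError(f"cannot open store at {path}: {e}") from e

    if "labels" not in root:
        raise FormatError(f"store at {path} has no 'labels' group")
    labels = root["labels"]
    lattrs = dict(labels.attrs)
    stack = labels[_first_scale_path(lattrs)][:]
    if stack.ndim == 2:
        stack = stack[None, ...]
    names = lattrs.get("channel_names")
    if not names or len(names) != stack.shape[0]:
        if strict:
            raise FormatError(
                f"store at {path} lacks channel_names metadata for its labels"
            )
        names = [f"channel_{i}" for i in range(stack.shape[0])]
        warnings.warn(f"{path}: assigning synthetic channel names", stacklevel=2)
    pixel_size = lattrs.get("pixel_size_um")
    mask = MultiChannelBitmask(
        [BitmaskChannel(nm, stack[i], pixel_size=pixel_size) for i, nm in enumerate(names)]
    )

    image = None
    if "image" in root:
        grp = root["image"]
        image = grp[_first_scale_path(dict(grp.attrs))][:]

    tables: dict[str, FeatureTable] = {}
    tdir = path / "tables"
    if tdir.is_dir():
        for sub in sorted(tdir.iterdir()):
            if sub.is_dir():
                t = _read_table_anndata(sub)
                tables[t.observation_type] = t

    return SegmentationDataset(bitmask=mask, image=image, tables=tables)


# ---------------------------------------------------------------------------
# CSV tables + JSON manifest
# ---------------------------------------------------------------------------

def read_tables_csv(manifest_path: PathLike) -> dict[str, FeatureTable]:
    """Read per-type CSV feature tables via their JSON linking manifest.

    Each CSV needs a header row with an ``id`` column of integers; remaining
    columns are parsed as float when numeric, otherwise kept as categorical
    text.  Row order is preserved (joins are by ID value regardless).
    """
    manifest_path = Path(manifest_path)
    try:
        entries = json.loads(manifest_path.read_text())
    except (OSError, json.JSONDecodeError) as e:
        raise ManifestError(f"cannot read manifest {manifest_path}: {e}") from e
    if not isinstance(entries, list):
        raise ManifestError("manifest must be a JSON list of entries")

    tables: dict[str, FeatureTable] = {}
    for entry in entries:
        try:
            uri, obs_type = entry["table"], entry["observation_type"]
        except (TypeError, KeyError) as e:
            raise ManifestError(f"malformed manifest entry {entry!r}") from e
        if obs_type in tables:
            raise ManifestError(f"duplicate observation_type {obs_type!r} in manifest")
        csv_path = Path(uri)
        if not csv_path.is_absolute():
            csv_path = manifest_path.parent / csv_path
        tables[obs_type] = _read_table_csv(csv_path, obs_type)
    return tables


def _read_table_csv(csv_path: Path, obs_type: str) -> FeatureTable:
    try:
        df = pd.read_csv(csv_path)
    except (OSError, pd.errors.ParserError) as e:
        raise ParseError(f"cannot parse CSV {csv_path}: {e}") from e
    if "id" not in df.columns:
        raise ParseError(f"{csv_path} has no 'id' column")
    ids = df["id"]
    if not pd.api.types.is_integer_dtype(ids):
        raise ParseError(f"{csv_path}: 'id' column is not integer-valued")
    body = df.drop(columns=["id"])
    out = pd.DataFrame(index=ids.to_numpy(dtype=np.int64))
    for c in body.columns:
        col = body[c]
        if pd.api.types.is_numeric_dtype(col):
            out[c] = col.to_numpy(dtype=np.float64)
        else:
            out[c] = pd.Categorical(col.astype(str)).set_categories(
                pd.unique(col.astype(str))
            )
    return FeatureTable(obs_type, out)


def write_tables_csv(
    tables: dict[str, FeatureTable],
    directory: PathLike,
    manifest_name: str = "manifest.json",
) -> Path:
    """Write one CSV per table plus the JSON manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for obs_type, table in tables.items():
        fname = f"{obs_type}.csv"
        df = table.data.copy()
        df.insert(0, "id", table.ids)
        df.to_csv(directory / fname, index=False)
        entries.append({"table": fname, "observation_type": obs_type})
    manifest = directory / manifest_name
    manifest.write_text(json.dumps(entries, indent=2))
    return manifest
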